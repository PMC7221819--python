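# Default physicochemical typing table (pseudocenter rules).
#
# Per residue:
#   ha  - atoms emitting a hydrogen-bond acceptor point each
#   hd  - atoms emitting a hydrogen-bond donor point each
#   had - atoms emitting a mixed donor/acceptor point each
#   aro - atom groups each emitting one aromatic point at the ring centroid
#   ali - contiguous aliphatic side-chain groups, each emitting one
#         hydrophobic point at the group centroid (Met SD counts as a member)
#
# Backbone rules apply to every standard residue: N -> HD (except proline),
# O -> HA, terminal OXT -> HA.
version: bsmm-default-1
backbone:
  N: HD
  O: HA
  OXT: HA
backbone_no_donor: [PRO]
residues:
  ALA:
    ali: [[CB]]
  ARG:
    hd: [NE, NH1, NH2]
    ali: [[CB, CG, CD]]
  ASN:
    ha: [OD1]
    hd: [ND2]
    ali: [[CB]]
  ASP:
    ha: [OD1, OD2]
    ali: [[CB]]
  CYS:
    had: [SG]
    ali: [[CB]]
  GLN:
    ha: [OE1]
    hd: [NE2]
    ali: [[CB, CG]]
  GLU:
    ha: [OE1, OE2]
    ali: [[CB, CG]]
  GLY: {}
  HIS:
    had: [ND1, NE2]
    aro: [[CG, ND1, CD2, CE1, NE2]]
    ali: [[CB]]
  ILE:
    ali: [[CB, CG1, CG2, CD1]]
  LEU:
    ali: [[CB, CG, CD1, CD2]]
  LYS:
    hd: [NZ]
    ali: [[CB, CG, CD, CE]]
  MET:
    ali: [[CB, CG, SD, CE]]
  PHE:
    aro: [[CG, CD1, CD2, CE1, CE2, CZ]]
    ali: [[CB]]
  PRO:
    ali: [[CB, CG, CD]]
  SER:
    had: [OG]
    ali: [[CB]]
  THR:
    had: [OG1]
    ali: [[CB, CG2]]
  TRP:
    hd: [NE1]
    aro: [[CG, CD1, NE1, CD2, CE2], [CD2, CE2, CE3, CZ2, CZ3, CH2]]
    ali: [[CB]]
  TYR:
    had: [OH]
    aro: [[CG, CD1, CD2, CE1, CE2, CZ]]
    ali: [[CB]]
  VAL:
    ali: [[CB, CG1, CG2]]
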