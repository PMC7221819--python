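"""Ligand-RMSD validation of site matches and a benchmark harness.

When two proteins bind the same ligand, the quality of a site match can be
judged without any manual reference: apply the match's query→reference
transform to the query complex's ligand and measure the RMSD against the
reference ligand.  A conserved binding mode yields a small RMSD; a match
whose transform lands the ligand far away (RMSD above 3.0 Å) either failed
or — as with imatinib bound to c-Kit versus Syk — reflects genuinely
different binding modes of the same compound.

The benchmark harness runs the full pipeline over a manifest of complex
pairs and tabulates scores, RMSDs and the good-match rate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import BsmmError
from .geohash import HashParams, build_hash
from .io_structures import ComplexRecord, read_complex
from .matching import (DEFAULT_D_CUTOFF, DEFAULT_GRID, DEFAULT_LINKAGE_CUTOFF,
                       DEFAULT_VOTE_THRESHOLD, MatchResult, MatchRules,
                       match_sites)
from .pc_typing import TypingTable
from .site_extraction import DEFAULT_CUTOFF, build_pc_site

logger = logging.getLogger(__name__)

GOOD_MATCH_RMSD = 3.0  # strict <

#: mscore bin edges used for the per-bin good-match summary
MSCORE_BINS = (0.0, 0.3, 0.5, 0.7, 0.9, 1.0 + 1e-9)


@dataclass
class EvalRecord:
    """One benchmark pair: identity, score and ligand-RMSD verdict."""

    pair_id: str
    ref_id: str
    qry_id: str
    ligand_code: str
    mscore: Optional[float] = None
    ligand_rmsd: Optional[float] = None
    good_match: Optional[bool] = None
    error: Optional[str] = None

    def as_row(self) -> dict:
        return {
            "pair_id": self.pair_id, "ref_id": self.ref_id,
            "qry_id": self.qry_id, "ligand_code": self.ligand_code,
            "mscore": self.mscore, "ligand_rmsd": self.ligand_rmsd,
            "good_match": self.good_match, "error": self.error,
        }


def ligand_rmsd(ref: ComplexRecord, qry: ComplexRecord,
                result: MatchResult) -> float:
    """RMSD between the reference ligand and the transformed query ligand.

    Atoms are corresponded by name within the shared chemical component; no
    graph-symmetry correction is applied, so symmetric or head-to-tail
    binders legitimately report large values.
    """
    if ref.ligand_code != qry.ligand_code:
        raise BsmmError(
            f"ligand codes differ: {ref.ligand_code} vs {qry.ligand_code}")
    if result.is_empty or result.rotation is None:
        raise BsmmError("empty match result has no transform to evaluate")
    ref_pos = {a.name: a.xyz for a in ref.ligand_atoms}
    qry_pos = {a.name: a.xyz for a in qry.ligand_atoms}
    common = sorted(set(ref_pos) & set(qry_pos))
    if len(common) < 3:
        raise BsmmError(
            f"only {len(common)} shared ligand atom names; need >= 3")
    P = np.array([ref_pos[n] for n in common])
    Q = np.array([qry_pos[n] for n in common])
    Qm = Q @ np.asarray(result.rotation).T + np.asarray(result.translation)
    return float(np.sqrt(((Qm - P) ** 2).sum(axis=1).mean()))


@dataclass
class BenchmarkParams:
    """Everything the end-to-end pipeline needs for one benchmark run."""

    cutoff: float = DEFAULT_CUTOFF
    hash_params: HashParams = field(default_factory=HashParams)
    vote_threshold: int = DEFAULT_VOTE_THRESHOLD
    grid: float = DEFAULT_GRID
    d_cutoff: float = DEFAULT_D_CUTOFF
    linkage_cutoff: float = DEFAULT_LINKAGE_CUTOFF
    table: Optional[TypingTable] = None


def evaluate_pair(ref_path, ref_selector, qry_path, qry_selector,
                  params: BenchmarkParams | None = None,
                  pair_id: str | None = None) -> EvalRecord:
    """Run the full pipeline on one complex pair and score it."""
    params = params or BenchmarkParams()
    pid = pair_id or f"{Path(ref_path).stem}|{Path(qry_path).stem}"
    rec = EvalRecord(pair_id=pid, ref_id=str(Path(ref_path).stem),
                     qry_id=str(Path(qry_path).stem), ligand_code="")
    try:
        ref = read_complex(ref_path, ref_selector)
        qry = read_complex(qry_path, qry_selector)
        rec.ligand_code = ref.ligand_code if ref.ligand_code == qry.ligand_code \
            else f"{ref.ligand_code}|{qry.ligand_code}"
        ref_site = build_pc_site(ref, table=params.table, cutoff=params.cutoff)
        qry_site = build_pc_site(qry, table=params.table, cutoff=params.cutoff)
        result = match_sites(build_hash(ref_site, params.hash_params),
                             build_hash(qry_site, params.hash_params),
                             vote_threshold=params.vote_threshold,
                             grid=params.grid, d_cutoff=params.d_cutoff,
                             linkage_cutoff=params.linkage_cutoff)
        rec.mscore = result.mscore
        if result.is_empty:
            rec.error = "no match above vote threshold"
        elif ref.ligand_code == qry.ligand_code:
            rec.ligand_rmsd = ligand_rmsd(ref, qry, result)
            rec.good_match = rec.ligand_rmsd < GOOD_MATCH_RMSD
    except BsmmError as exc:
        rec.error = str(exc)
        logger.warning("pair %s failed: %s", pid, exc)
    return rec


def summarize(records: Sequence[EvalRecord]) -> dict:
    """Exact summary recomputable from the per-pair table."""
    scored = [r for r in records if r.good_match is not None]
    n_good = sum(1 for r in scored if r.good_match)
    summary = {
        "n_pairs": len(records),
        "n_scored": len(scored),
        "n_failed": sum(1 for r in records if r.error is not None),
        "n_good": n_good,
        "good_match_rate": (n_good / len(scored)) if scored else None,
        "by_mscore_bin": [],
    }
    for lo, hi in zip(MSCORE_BINS[:-1], MSCORE_BINS[1:]):
        inbin = [r for r in scored if r.mscore is not None
                 and lo <= r.mscore < hi]
        summary["by_mscore_bin"].append({
            "mscore_min": lo, "mscore_max": min(hi, 1.0),
            "n": len(inbin),
            "n_good": sum(1 for r in inbin if r.good_match),
            "good_match_rate": (sum(1 for r in inbin if r.good_match)
                                / len(inbin)) if inbin else None,
        })
    return summary


def read_manifest(path) -> list:
    """Parse a CSV manifest: ref_pdb, ref_lig, qry_pdb, qry_lig[, pair_id, ...].

    Ligand selectors are ``CODE``, ``CODE:CHAIN`` or ``CODE:CHAIN:RESNUM``.
    Extra columns are carried along as metadata, never computed.
    """
    df = pd.read_csv(path, comment="#", skipinitialspace=True, dtype=str)
    required = {"ref_pdb", "ref_lig", "qry_pdb", "qry_lig"}
    missing = required - set(df.columns)
    if missing:
        raise BsmmError(f"manifest missing columns: {sorted(missing)}")
    rows = []
    base = Path(path).parent
    for i, row in df.iterrows():
        ref_pdb = Path(row["ref_pdb"])
        qry_pdb = Path(row["qry_pdb"])
        rows.append({
            "pair_id": row.get("pair_id") or f"pair{i + 1}",
            "ref_pdb": ref_pdb if ref_pdb.is_absolute() else base / ref_pdb,
            "ref_lig": row["ref_lig"],
            "qry_pdb": qry_pdb if qry_pdb.is_absolute() else base / qry_pdb,
            "qry_lig": row["qry_lig"],
        })
    return rows


def run_benchmark(manifest, params: BenchmarkParams | None = None):
    """Evaluate every pair of a manifest; failures are recorded, not fatal.

    ``manifest`` is a path to a CSV file or a pre-parsed list of dicts.
    Returns ``(DataFrame, summary dict)``.
    """
    if not isinstance(manifest, (list, tuple)):
        manifest = read_manifest(manifest)
    records = []
    for row in manifest:
        records.append(evaluate_pair(
            row["ref_pdb"], row["ref_lig"], row["qry_pdb"], row["qry_lig"],
            params=params, pair_id=row.get("pair_id")))
    df = pd.DataFrame([r.as_row() for r in records],
                      columns=["pair_id", "ref_id", "qry_id", "ligand_code",
                               "mscore", "ligand_rmsd", "good_match", "error"])
    return df, summarize(records)


def write_benchmark(df: pd.DataFrame, summary: dict, out_dir) -> dict:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "benchmark.csv"
    json_path = out_dir / "benchmark_summary.json"
    df.to_csv(csv_path, index=False)
    json_path.write_text(json.dumps(summary, indent=1) + "\n")
    return {"csv": csv_path, "summary": json_path}
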