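"""Exception hierarchy for the bsmm package."""


class BsmmError(Exception):
    """Base class for all bsmm-specific errors."""


class ParseError(BsmmError):
    """The input structure file could not be parsed."""


class LigandNotFoundError(BsmmError):
    """No HET group matched the ligand selector."""


class AmbiguousLigandError(BsmmError):
    """More than one HET group matched an under-specified selector."""

    def __init__(self, code: str, candidates):
        self.code = code
        self.candidates = list(candidates)
        listing = ", ".join(f"{c[0]}/{c[1]}{c[2]}" for c in self.candidates)
        super().__init__(
            f"ligand {code!r} is ambiguous; specify chain/residue number "
            f"(candidates: {listing})"
        )


class EmptySiteError(BsmmError):
    """No residues were found within the ligand-proximity cutoff."""


class SiteTooSmallError(BsmmError):
    """Fewer than three PC points survive; the site cannot be hashed."""


class DegenerateGeometryError(BsmmError):
    """Collinear or otherwise degenerate point configuration."""


class HashingError(BsmmError):
    """No admissible reference triangle could be built from the site."""
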