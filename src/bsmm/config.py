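"""Run configuration: every tunable parameter plus a provenance stamp."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__


@dataclass
class RunConfig:
    """All pipeline knobs with their standard defaults.

    The defaults mirror the method's published operating point: a 6.0 Å
    site cutoff, 1.0 Å grid, vote threshold 7 (i.e. "vote > 6") and a
    strict 3.0 Å extension cutoff.
    """

    cutoff: float = 6.0            # ligand-proximity cutoff, Angstrom
    grid: float = 1.0              # voting grid bin width, Angstrom
    d_min: float = 2.0             # shortest admissible triangle side
    d_max: float = 13.0            # longest admissible triangle side
    vote_threshold: int = 7        # votes required (>= semantics)
    d_cutoff: float = 3.0          # extension distance cutoff (strict <)
    linkage_cutoff: float = 5.0    # subsite single-linkage cutoff
    top_k: int = 5                 # ranked alternatives to keep
    typing_table: Optional[str] = None  # path; None -> shipped default
    prefilter: bool = True

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_file(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def parameter_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def provenance(self) -> dict:
        return {"tool": "bsmm", "version": __version__,
                "parameter_hash": self.parameter_hash(),
                "parameters": self.to_dict()}
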