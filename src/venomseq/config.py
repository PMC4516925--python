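"""Run configuration: tolerances, windows and fitting defaults.

All mass tolerances are absolute daltons, matching the externally
calibrated MALDI-TOF regime the defaults were chosen for.  A RunConfig is
serialised into every report so results carry their provenance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    ladder_tol: float = 0.3       # Da, ISD ladder steps
    pmf_tol: float = 0.5          # Da, peptide mass fingerprint matching
    msms_tol: float = 0.3         # Da, b/y ion annotation
    cpy_tol: float = 0.3          # Da, CPY step reading
    mature_mass_tol: float = 0.25  # Da, mature-peptide delimitation
    amide_window: tuple[float, float] = (0.6, 1.3)  # Da deficit calling amide
    free_acid_tol: float = 0.3    # Da, |deficit| calling free acid
    max_missed: int = 2           # tryptic missed cleavages
    max_mismatch: int = 1         # tag-search mismatch budget
    min_orf_aa: int = 30
    vrev: float = 65.0            # mV, fixed sodium reversal potential
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self) -> None:
        for name in (
            "ladder_tol", "pmf_tol", "msms_tol", "cpy_tol", "mature_mass_tol",
            "free_acid_tol",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.amide_window = tuple(self.amide_window)  # type: ignore[assignment]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["amide_window"] = list(self.amide_window)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
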