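"""Record types shared by the analysis and simulation modules."""

from __future__ import annotations

from dataclasses import dataclass

#: Canonical ordering of follicle stages plus the offspring reference level.
STAGES = (
    "primordial",
    "primary",
    "early_secondary",
    "late_secondary",
    "antral",
    "MII",
    "offspring",
)


@dataclass(frozen=True)
class TransmissionPair:
    """One mother-to-pup heteroplasmy observation with pedigree covariates.

    Heteroplasmies are fractions.  ``mother_h`` must be interior (0, 1) for a
    pair to enter shift analyses; boundary pups are handled by the caller's
    boundary policy.
    """

    mother_id: str
    pup_id: str
    generation: str
    mother_h: float
    pup_h: float
    maternal_age_months: float | None = None
    litter_id: str | None = None
    litter_size: int | None = None

    def __post_init__(self):
        if not (0.0 <= self.mother_h <= 1.0 and 0.0 <= self.pup_h <= 1.0):
            raise ValueError("heteroplasmy values must lie in [0, 1]")
        if self.litter_size is not None and self.litter_size < 1:
            raise ValueError("litter_size must be >= 1 when present")


@dataclass(frozen=True)
class OocyteRecord:
    """Per-oocyte heteroplasmy (and optional WT/mutant copy numbers) at a
    follicle stage (in vivo) or culture day (in vitro)."""

    mouse_id: str
    mother_h: float
    h: float
    stage: str | None = None
    day: int | None = None
    wt_copies: float | None = None
    mut_copies: float | None = None
    group: str = "edited"

    def __post_init__(self):
        if self.stage is None and self.day is None:
            raise ValueError("an oocyte record needs a stage or a culture day")
        if self.day is not None and not (0 <= self.day <= 7):
            raise ValueError("culture day must lie in [0, 7]")
        for name in ("wt_copies", "mut_copies"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total_copies(self) -> float | None:
        if self.wt_copies is None or self.mut_copies is None:
            return None
        return self.wt_copies + self.mut_copies
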