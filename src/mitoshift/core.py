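"""Heteroplasmy value types, shift transforms, ddPCR quantification and the
conversion-rate off-target caller.

Heteroplasmy is carried internally as a fraction in [0, 1].  Percent-scale
columns are converted exactly once at the I/O boundary (see
:mod:`mitoshift.io`) and never stored internally.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    BoundaryHeteroplasmyError,
    SaturationError,
    UndefinedReferenceError,
)

__all__ = [
    "ShiftResult",
    "DdpcrWell",
    "CopyEstimate",
    "SiteCounts",
    "OfftargetCall",
    "validate_heteroplasmy",
    "shift_ratio",
    "log_shift",
    "heteroplasmy_shift",
    "log_shifts",
    "shift_ratios",
    "ddpcr_quantify",
    "call_offtargets",
    "DEFAULT_DROPLET_VOLUME_NL",
]

#: QX200 convention; only used for optional copies/µL reporting.
DEFAULT_DROPLET_VOLUME_NL = 0.85


def validate_heteroplasmy(value: float, name: str = "heteroplasmy") -> float:
    """Check that ``value`` is a fraction in [0, 1] and return it as float."""
    v = float(value)
    if not (0.0 <= v <= 1.0) or math.isnan(v):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
    return v


@dataclass(frozen=True)
class ShiftResult:
    """Offspring-vs-mother heteroplasmy shift.

    ``ratio`` is the odds ratio of mutant carriage in the offspring relative
    to the mother; ``log_shift`` is its natural log, i.e. the difference of
    logits.  ``ratio == 1`` (``log_shift == 0``) means unbiased transmission,
    values below 1 (negative logs) a reduction in the offspring.
    """

    ratio: float
    log_shift: float


def shift_ratio(h: float, h0: float) -> float:
    """Heteroplasmy shift ratio ``h(1-h0) / (h0(1-h))``.

    Parameters
    ----------
    h : float
        Offspring (pup/oocyte) heteroplasmy fraction; ``0 <= h < 1``.
    h0 : float
        Maternal reference heteroplasmy fraction; ``0 < h0 < 1``.

    Raises
    ------
    UndefinedReferenceError
        If ``h0`` is 0 or 1 (the odds of the reference are 0 or infinite).
    SaturationError
        If ``h`` is 1 (mutation fixed in the offspring; ratio infinite).
    """
    h = validate_heteroplasmy(h, "h")
    h0 = validate_heteroplasmy(h0, "h0")
    if h0 <= 0.0 or h0 >= 1.0:
        raise UndefinedReferenceError(
            f"reference heteroplasmy h0={h0} has undefined odds"
        )
    if h >= 1.0:
        raise SaturationError("offspring heteroplasmy is fixed (h = 1)")
    return (h * (1.0 - h0)) / (h0 * (1.0 - h))


def log_shift(h: float, h0: float) -> float:
    """Log heteroplasmy shift ``ln(h(1-h0) / (h0(1-h))) = logit(h) - logit(h0)``.

    Antisymmetric under swapping ``h`` and ``h0`` and additive across chained
    transmissions.  Both arguments must be strictly inside (0, 1).
    """
    h = validate_heteroplasmy(h, "h")
    h0 = validate_heteroplasmy(h0, "h0")
    if h <= 0.0 or h >= 1.0 or h0 <= 0.0 or h0 >= 1.0:
        raise BoundaryHeteroplasmyError(
            f"log shift requires interior heteroplasmy, got h={h}, h0={h0}"
        )
    # logit difference; algebraically identical to ln(shift_ratio)
    return math.log(h / (1.0 - h)) - math.log(h0 / (1.0 - h0))


def heteroplasmy_shift(h: float, h0: float) -> ShiftResult:
    """Compute both the ratio and log forms of the shift at once."""
    r = shift_ratio(h, h0)
    if h <= 0.0:
        raise BoundaryHeteroplasmyError("log shift undefined for h = 0")
    return ShiftResult(ratio=r, log_shift=math.log(r))


def _clamp_eps(assay_copies: int | None) -> float:
    if assay_copies is not None and assay_copies > 0:
        return 1.0 / (2.0 * assay_copies)
    return 1e-4


def log_shifts(
    h: Sequence[float],
    h0: Sequence[float],
    policy: str = "exclude",
    assay_copies: int | None = None,
) -> tuple[np.ndarray, int]:
    """Vectorised log shifts with a boundary policy.

    Records with ``h`` or ``h0`` at 0 or 1 are either dropped
    (``policy="exclude"``, the default, with a warning) or clamped to
    ``[eps, 1-eps]`` with ``eps = 1/(2*assay_copies)`` (``policy="clamp"``).

    Returns
    -------
    (values, n_excluded) : (ndarray, int)
        Log shifts of the retained records and the number of excluded ones
        (always 0 under the clamp policy).
    """
    h = np.asarray(h, dtype=float)
    h0 = np.asarray(h0, dtype=float)
    if h.shape != h0.shape:
        raise ValueError("h and h0 must have matching shapes")
    if np.any((h < 0) | (h > 1)) or np.any((h0 < 0) | (h0 > 1)):
        raise ValueError("heteroplasmy values must lie in [0, 1]")
    if policy == "clamp":
        eps = _clamp_eps(assay_copies)
        h = np.clip(h, eps, 1.0 - eps)
        h0 = np.clip(h0, eps, 1.0 - eps)
        keep = np.ones(h.shape, dtype=bool)
    elif policy == "exclude":
        keep = (h > 0) & (h < 1) & (h0 > 0) & (h0 < 1)
        if not keep.all():
            warnings.warn(
                f"excluded {int((~keep).sum())} record(s) with boundary "
                "heteroplasmy from log-shift analysis",
                stacklevel=2,
            )
    else:
        raise ValueError(f"unknown boundary policy {policy!r}")
    hk, h0k = h[keep], h0[keep]
    vals = np.log(hk / (1.0 - hk)) - np.log(h0k / (1.0 - h0k))
    return vals, int((~keep).sum())


def shift_ratios(h: Sequence[float], h0: Sequence[float]) -> np.ndarray:
    """Vectorised shift ratios; requires interior ``h0`` and ``h < 1``."""
    h = np.asarray(h, dtype=float)
    h0 = np.asarray(h0, dtype=float)
    if np.any((h0 <= 0) | (h0 >= 1)):
        raise UndefinedReferenceError("all reference heteroplasmies must be in (0,1)")
    if np.any(h >= 1):
        raise SaturationError("offspring heteroplasmy of 1 has infinite ratio")
    return (h * (1.0 - h0)) / (h0 * (1.0 - h))


# ---------------------------------------------------------------------------
# ddPCR Poisson quantification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DdpcrWell:
    """Droplet counts for one ddPCR well.

    FAM counts droplets positive in the wild-type channel, HEX those positive
    in the mutant channel.
    """

    sample_id: str
    droplets_total: int
    fam_positive: int
    hex_positive: int
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL

    def __post_init__(self):
        if self.droplets_total <= 0:
            raise ValueError("droplets_total must be positive")
        for name in ("fam_positive", "hex_positive"):
            k = getattr(self, name)
            if not (0 <= k <= self.droplets_total):
                raise ValueError(f"{name}={k} outside [0, droplets_total]")


@dataclass(frozen=True)
class CopyEstimate:
    """Poisson-corrected template molecule counts for one reaction."""

    sample_id: str
    wt_copies: float
    mut_copies: float
    total_copies: float
    heteroplasmy: float | None
    copies_per_ul: float | None = None
    empty: bool = False


def _poisson_lambda(positive: int, total: int, channel: str) -> float:
    if positive >= total:
        raise SaturationError(
            f"{channel} channel saturated ({positive}/{total} droplets positive)"
        )
    return -math.log(1.0 - positive / total)


def ddpcr_quantify(well: DdpcrWell) -> CopyEstimate:
    """Estimate template copies per reaction from droplet counts.

    Per channel the mean molecules per droplet is ``lambda = -ln(1 - k/N)``
    and the per-reaction copy count ``lambda * N``.  Heteroplasmy is the
    lambda ratio ``lambda_hex / (lambda_hex + lambda_fam)``, which corrects
    for droplets holding more than one molecule.  A well with no positive
    droplet in either channel is flagged ``empty`` with heteroplasmy ``None``.

    Raises
    ------
    SaturationError
        If every droplet is positive in a channel (lambda unbounded).
    """
    n = well.droplets_total
    lam_fam = _poisson_lambda(well.fam_positive, n, "FAM")
    lam_hex = _poisson_lambda(well.hex_positive, n, "HEX")
    wt = lam_fam * n
    mut = lam_hex * n
    total = wt + mut
    if total > 0:
        het = mut / total
        empty = False
    else:
        het = None
        empty = True
        warnings.warn(f"well {well.sample_id!r} is empty; heteroplasmy undefined",
                      stacklevel=2)
    volume_ul = n * well.droplet_volume_nl * 1e-3
    per_ul = total / volume_ul if volume_ul > 0 else None
    return CopyEstimate(
        sample_id=well.sample_id,
        wt_copies=wt,
        mut_copies=mut,
        total_copies=total,
        heteroplasmy=het,
        copies_per_ul=per_ul,
        empty=empty,
    )


# ---------------------------------------------------------------------------
# Conversion-rate off-target calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteCounts:
    """Per-position base counts on the mitochondrial reference (1-based)."""

    position: int
    ref_base: str
    count_a: int
    count_c: int
    count_g: int
    count_t: int

    @property
    def depth(self) -> int:
        return self.count_a + self.count_c + self.count_g + self.count_t


@dataclass(frozen=True)
class OfftargetCall:
    position: int
    edit_class: str  # "C>T" or "G>A"
    conversion_rate: float
    flagged: bool


def call_offtargets(
    sites: Iterable[SiteCounts],
    threshold: float = 0.01,
    exclude: Iterable[int] = (),
) -> list[OfftargetCall]:
    """Flag C/G positions whose deaminase conversion rate meets ``threshold``.

    For a reference C the conversion rate is ``count_t / depth`` (C>T); for a
    reference G it is ``count_a / depth`` (G>A).  The comparison is inclusive
    (``rate >= threshold``).  Reference A/T sites are never evaluated, and
    positions listed in ``exclude`` (intended on-target edits) are reported
    but never flagged.  Zero-depth sites are skipped with a warning.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    excluded = set(int(p) for p in exclude)
    calls: list[OfftargetCall] = []
    for site in sites:
        ref = site.ref_base.upper()
        if ref in ("A", "T"):
            continue
        if ref not in ("C", "G"):
            raise ValueError(f"unknown reference base {site.ref_base!r} "
                             f"at position {site.position}")
        depth = site.depth
        if depth == 0:
            warnings.warn(f"position {site.position}: zero depth, skipped",
                          stacklevel=2)
            continue
        if ref == "C":
            rate = site.count_t / depth
            edit_class = "C>T"
        else:
            rate = site.count_a / depth
            edit_class = "G>A"
        flagged = rate >= threshold and site.position not in excluded
        calls.append(OfftargetCall(site.position, edit_class, rate, flagged))
    return calls
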