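"""Synthetic data generators emulating the study's data-generating processes.

Four generators cover the analysis surface end to end: a bottleneck/selection
pedigree simulator, a follicle copy-number time course with mutant
elimination and compensatory wild-type replication, a droplet-partitioning
ddPCR observation model, and a base-editing pileup fixture generator.  All
are deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import DdpcrWell, SiteCounts
from .records import OocyteRecord, TransmissionPair

__all__ = [
    "PedigreeSimConfig",
    "FollicleSimConfig",
    "simulate_pedigree",
    "simulate_follicle_timecourse",
    "simulate_ddpcr",
    "simulate_site_counts",
    "wright_fisher_transmit",
]


@dataclass(frozen=True)
class PedigreeSimConfig:
    """Forward model for one round of germline transmission.

    Each pup's heteroplasmy evolves from its mother's value through
    ``generations_per_transmission`` Wright-Fisher generations at
    ``bottleneck_n`` segregating copies.  ``selection_s`` is the
    per-replication relative fitness deviation of mutant copies (0 neutral,
    negative purifying); each generation the post-selection frequency is
    ``p' = p(1+s) / (1 + p*s)``.  Measured pup heteroplasmy adds binomial
    noise at ``measurement_copies`` assay copies; maternal values are taken
    as measured exactly so the neutral regression slope stays 1.
    """

    founder_h: float = 0.0672
    n_mothers: int = 44
    pups_per_mother: int = 18
    bottleneck_n: int = 200
    generations_per_transmission: int = 15
    selection_s: float = 0.0
    measurement_copies: int = 20000
    mean_litter_size: float = 8.0
    age_at_first_litter_months: float = 3.0
    months_between_litters: float = 1.5
    age_shift_per_month: float = 0.0  # optional injected age trend (logit/month)
    seed: int = 0

    def __post_init__(self):
        if self.bottleneck_n < 2:
            raise ValueError("bottleneck_n must be >= 2")
        if self.generations_per_transmission < 1:
            raise ValueError("generations_per_transmission must be >= 1")
        if self.selection_s <= -1.0:
            raise ValueError("selection_s must be > -1")
        if not (0.0 < self.founder_h < 1.0):
            raise ValueError("founder_h must be interior (0, 1)")


def wright_fisher_transmit(
    h0: np.ndarray,
    bottleneck_n: int,
    generations: int,
    selection_s: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised Wright-Fisher drift with haploid per-replication selection.

    Each entry of ``h0`` evolves independently for ``generations`` binomial
    resampling steps at ``bottleneck_n`` copies, applying the post-selection
    frequency ``p' = p(1+s)/(1+p*s)`` before every resampling step.
    """
    p = np.asarray(h0, dtype=float).copy()
    s = selection_s
    n = bottleneck_n
    for _ in range(generations):
        if s != 0.0:
            p = p * (1.0 + s) / (1.0 + p * s)
        p = rng.binomial(n, p) / n
    return p


def simulate_pedigree(config: PedigreeSimConfig) -> list[TransmissionPair]:
    """Generate fully-populated mother-to-pup transmission records.

    Mothers are produced by one neutral transmission from the founder
    (redrawn while at a heteroplasmy boundary, so every mother is usable as a
    reference).  Pups are grouped into litters of Poisson-distributed size;
    maternal age advances between litters.  Litter sizes and ages are
    independent of heteroplasmy unless ``age_shift_per_month`` is nonzero,
    in which case an extra logit shift proportional to maternal age is
    applied to each pup (power-testing knob for the age analysis).
    """
    rng = np.random.default_rng(config.seed)
    n_m = config.n_mothers

    mother_h = np.full(n_m, config.founder_h)
    mother_h = wright_fisher_transmit(
        mother_h, config.bottleneck_n, config.generations_per_transmission,
        0.0, rng)
    for _ in range(100):
        bad = (mother_h <= 0.0) | (mother_h >= 1.0)
        if not bad.any():
            break
        redraw = np.full(int(bad.sum()), config.founder_h)
        mother_h[bad] = wright_fisher_transmit(
            redraw, config.bottleneck_n, config.generations_per_transmission,
            0.0, rng)
    else:  # pragma: no cover - essentially impossible for sane configs
        raise RuntimeError("could not draw interior maternal heteroplasmies")

    pairs: list[TransmissionPair] = []
    for j in range(n_m):
        mid = f"M{j:03d}"
        h0 = float(mother_h[j])
        # split this mother's pups into litters
        remaining = config.pups_per_mother
        litter_no = 0
        while remaining > 0:
            size = int(min(remaining,
                           max(1, rng.poisson(config.mean_litter_size))))
            age = (config.age_at_first_litter_months
                   + litter_no * config.months_between_litters)
            h_true = wright_fisher_transmit(
                np.full(size, h0), config.bottleneck_n,
                config.generations_per_transmission, config.selection_s, rng)
            if config.age_shift_per_month != 0.0:
                interior = (h_true > 0) & (h_true < 1)
                shift = config.age_shift_per_month * age
                logit = np.log(h_true[interior] / (1 - h_true[interior])) + shift
                h_true[interior] = 1.0 / (1.0 + np.exp(-logit))
            h_meas = rng.binomial(config.measurement_copies, h_true) \
                / config.measurement_copies
            for k in range(size):
                pairs.append(TransmissionPair(
                    mother_id=mid,
                    pup_id=f"{mid}.L{litter_no}.P{k}",
                    generation="F2",
                    mother_h=h0,
                    pup_h=float(h_meas[k]),
                    maternal_age_months=age,
                    litter_id=f"{mid}.L{litter_no}",
                    litter_size=size,
                ))
            remaining -= size
            litter_no += 1
    return pairs


# ---------------------------------------------------------------------------
# Follicle copy-number time course
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FollicleSimConfig:
    """Per-oocyte mtDNA copy dynamics over up to 7 culture days.

    Wild-type copies replicate to fill the deficit toward ``target_copies``;
    mutant copies are removed with per-day per-copy probability
    ``elimination_rate_delta`` and excluded from compensatory replication
    (set ``mutant_replication_fraction`` above 0 for sensitivity analysis).
    """

    n_oocytes: int = 30
    initial_total_copies: int = 20000
    initial_h: float = 0.3
    target_copies: int = 100_000
    replication_rate: float = 0.6
    elimination_rate_delta: float = 0.35
    days: Sequence[int] = tuple(range(8))
    group: str = "edited"
    mutant_replication_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.target_copies <= self.initial_total_copies:
            raise ValueError("target_copies must exceed initial_total_copies")
        if not (0.0 <= self.elimination_rate_delta <= 1.0):
            raise ValueError("elimination_rate_delta must lie in [0, 1]")
        if not (0.0 <= self.initial_h <= 1.0):
            raise ValueError("initial_h must lie in [0, 1]")
        if any(d < 0 or d > 7 for d in self.days):
            raise ValueError("sampled days must lie in [0, 7]")


def simulate_follicle_timecourse(config: FollicleSimConfig) -> list[OocyteRecord]:
    """Daily stochastic update of WT/mutant copy counts per oocyte.

    Per day: each mutant copy survives with probability ``1 - delta``
    (binomial thinning); the copy deficit toward the target is filled by
    wild-type replication as a binomial draw with the per-day replication
    rate.  Records are emitted for every requested day, including day 0.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_oocytes
    mut = rng.binomial(config.initial_total_copies,
                       config.initial_h, size=n).astype(np.int64)
    wt = config.initial_total_copies - mut
    mother_h = config.initial_h if 0.0 < config.initial_h < 1.0 else 0.5

    wanted = set(int(d) for d in config.days)
    records: list[OocyteRecord] = []

    def emit(day: int):
        for i in range(n):
            total = wt[i] + mut[i]
            records.append(OocyteRecord(
                mouse_id=f"O{i:03d}",
                mother_h=mother_h,
                h=float(mut[i] / total) if total > 0 else 0.0,
                day=day,
                wt_copies=float(wt[i]),
                mut_copies=float(mut[i]),
                group=config.group,
            ))

    if 0 in wanted:
        emit(0)
    for day in range(1, 8):
        mut = rng.binomial(mut, 1.0 - config.elimination_rate_delta)
        deficit = np.maximum(config.target_copies - (wt + mut), 0)
        growth = rng.binomial(deficit, config.replication_rate)
        if config.mutant_replication_fraction > 0.0:
            totals = wt + mut
            mut_share = np.where(
                totals > 0,
                config.mutant_replication_fraction * mut / np.maximum(totals, 1),
                0.0)
            mut_growth = rng.binomial(growth, mut_share)
            mut = mut + mut_growth
            wt = wt + growth - mut_growth
        else:
            wt = wt + growth
        if day in wanted:
            emit(day)
    return records


# ---------------------------------------------------------------------------
# ddPCR observation model
# ---------------------------------------------------------------------------

def simulate_ddpcr(copies_wt: float, copies_mut: float, droplets: int,
                   seed: np.random.Generator | int | None = 0,
                   sample_id: str = "sim") -> DdpcrWell:
    """Partition molecules over droplets and count channel-positive droplets.

    Under independent Poisson occupancy with per-channel mean
    ``copies / droplets``, the number of positive droplets in a channel is
    ``Binomial(droplets, 1 - exp(-lambda))``, which is drawn directly.
    """
    if droplets < 1:
        raise ValueError("droplets must be >= 1")
    if copies_wt < 0 or copies_mut < 0:
        raise ValueError("copy counts must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    lam_fam = copies_wt / droplets
    lam_hex = copies_mut / droplets
    fam = int(rng.binomial(droplets, 1.0 - np.exp(-lam_fam)))
    hex_ = int(rng.binomial(droplets, 1.0 - np.exp(-lam_hex)))
    return DdpcrWell(sample_id=sample_id, droplets_total=droplets,
                     fam_positive=fam, hex_positive=hex_)


# ---------------------------------------------------------------------------
# Base-editing pileup fixture
# ---------------------------------------------------------------------------

def simulate_site_counts(
    n_sites: int,
    depth: int,
    edit_positions: Mapping[int, float] | None = None,
    sequencing_error: float = 0.001,
    seed: np.random.Generator | int | None = 0,
) -> list[SiteCounts]:
    """Per-site base counts with deaminase edits at chosen positions.

    Reference bases cycle deterministically through C, G, A, T (positions are
    1-based).  At a C (G) site the C>T (G>A) conversion count is binomial at
    the site's edit rate plus the uniform per-base sequencing error; the
    error also scatters reads onto the remaining two non-reference bases.
    Positions absent from ``edit_positions`` have edit rate 0.

    Raises
    ------
    ValueError
        If an edit position falls on a reference A/T site (no deaminase
        substrate there) or rates are out of range.
    """
    if not (0.0 <= sequencing_error <= 0.01):
        raise ValueError("sequencing_error must lie in [0, 0.01]")
    edit_positions = dict(edit_positions or {})
    bases = "CGAT"
    ref_of = {pos: bases[(pos - 1) % 4] for pos in range(1, n_sites + 1)}
    for pos, rate in edit_positions.items():
        if not (1 <= pos <= n_sites):
            raise ValueError(f"edit position {pos} outside 1..{n_sites}")
        if ref_of[pos] not in "CG":
            raise ValueError(f"edit position {pos} has reference {ref_of[pos]}; "
                             "deaminase edits need a C or G")
        if not (0.0 <= rate <= 1.0):
            raise ValueError("edit rates must lie in [0, 1]")

    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    conv_target = {"C": "T", "G": "A", "A": "G", "T": "C"}
    sites: list[SiteCounts] = []
    for pos in range(1, n_sites + 1):
        ref = ref_of[pos]
        rate = edit_positions.get(pos, 0.0)
        counts = {b: 0 for b in "ACGT"}
        conv = int(rng.binomial(depth, min(1.0, rate + sequencing_error)))
        others = [b for b in "ACGT" if b not in (ref, conv_target[ref])]
        e1 = int(rng.binomial(depth - conv, sequencing_error))
        e2 = int(rng.binomial(depth - conv - e1, sequencing_error))
        counts[conv_target[ref]] = conv
        counts[others[0]] = e1
        counts[others[1]] = e2
        counts[ref] = depth - conv - e1 - e2
        sites.append(SiteCounts(position=pos, ref_base=ref,
                                count_a=counts["A"], count_c=counts["C"],
                                count_g=counts["G"], count_t=counts["T"]))
    return sites
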