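"""Stochastic model of ribosome translation over a single codon of interest.

The model coarse-grains translation of one mRNA into three stages centred on
a focal codon (the site of a synonymous SNP): initiation plus elongation of
the upstream subsequence, decoding of the focal codon by its cognate tRNA,
and elongation of the downstream subsequence followed by release of all
components.  Each stage is a mass-action reaction whose products reappear
only after a fixed delay, so the model runs on the delayed SSA engine.

Species
-------
``Rib``, ``mRNA1``, ``mRNA2``, ``tRNA``, ``Prot`` plus three intermediate
complexes.  ``mRNA1`` and ``mRNA2`` are bookkeeping halves of a single
physical mRNA — the subsequences before and after the focal codon — labelled
separately so that the codon step can be given its own rate and delay.
Ribosomes, mRNAs and tRNAs are conserved: every molecule that enters a
complex or the waitlist eventually returns to its free pool.  Only the
protein is produced and degraded.

Reactions (rates 1/s or 1/(molecule*s); delays in parentheses, seconds)::

    R1  Rib + mRNA1        --k_p1-->      C1 (tau_p1)
    R2  C1 + tRNA          --k_codon-->   C2 (tau_codon) + tRNA (tau_codon)
    R3  C2 + mRNA2         --k_p1-->      C3 (tau_p2)
    R4  C3                 --k_release--> mRNA1 (tau_mRNA) + mRNA2 (tau_mRNA)
                                          + Rib (tau_Rib) + Prot (tau_prot)
    R5  Prot               --k_P_decay--> (nothing)

where ``C1 = p1.Rib.mRNA1``, ``C2 = snp.p1.Rib.mRNA1``,
``C3 = mRNA2.snp.p1.Rib.mRNA1``.  The codon step's rate ``k_codon`` models
cognate-tRNA availability: an abundant tRNA decodes the codon fast, a scarce
one stalls the ribosome on ``C1``.  A variant (WT or SNP) is fully specified
by its ``(k_codon, tau_codon)`` pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ssa import DelayedProduct, Reaction, ReactionNetwork, Species, Trajectory, simulate

__all__ = [
    "TranslationParameters",
    "VariantSpec",
    "ReplicateSummary",
    "SweepResult",
    "WT_REFERENCE",
    "K_SNP_GRID",
    "TAU_SNP_GRID",
    "SPECIES",
    "build_translation_network",
    "simulate_variant",
    "posttransient_mean_protein",
    "time_weighted_mean",
    "run_replicates",
    "sweep_ratio",
    "conservation_totals",
]

# species names follow the complex labelling of the reaction scheme
SPECIES = (
    "Rib",
    "mRNA1",
    "mRNA2",
    "tRNA",
    "Prot",
    "p1.Rib.mRNA1",
    "snp.p1.Rib.mRNA1",
    "mRNA2.snp.p1.Rib.mRNA1",
)
_C1, _C2, _C3 = SPECIES[5], SPECIES[6], SPECIES[7]

#: codon-rate grid swept for the SNP variant, 1/(molecule*s)
K_SNP_GRID: tuple[float, ...] = (0.4e-3, 0.8e-3, 1.6e-3, 4e-3)
#: codon-delay grid swept for the SNP variant, s
TAU_SNP_GRID: tuple[float, ...] = (0.1, 1.0, 5.0)


@dataclass(frozen=True)
class TranslationParameters:
    """All rate constants, delays and initial copy numbers of the model.

    Defaults are the reference parameter set: rates in 1/s (bimolecular
    rates in 1/(molecule*s)), delays in s, counts in molecules.
    """

    k_p1: float = 0.01  # ribosome/mRNA association, also used for R3
    k_release: float = 1.0  # unimolecular completion rate of R4
    k_P_decay: float = 3e-4  # protein degradation
    tau_p1: float = 10.0  # elongation time of the upstream subsequence
    tau_p2: float = 25.0  # elongation time of the downstream subsequence
    tau_mRNA: float = 5.0  # mRNA halves return to the pool
    tau_Rib: float = 50.0  # ribosome recycling
    tau_prot: float = 300.0  # protein maturation/folding before it counts
    rib0: int = 100
    mrna1_0: int = 50
    mrna2_0: int = 50
    trna0: int = 50
    prot0: int = 0

    def __post_init__(self) -> None:
        for name in ("k_p1", "k_release", "k_P_decay"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("tau_p1", "tau_p2", "tau_mRNA", "tau_Rib", "tau_prot"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("rib0", "mrna1_0", "mrna2_0", "trna0", "prot0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class VariantSpec:
    """Codon kinetics of one allele: decoding rate and decoding delay."""

    label: str
    k_codon: float  # 1/(molecule*s)
    tau_codon: float  # s

    def __post_init__(self) -> None:
        if not self.k_codon > 0:
            raise ValueError("k_codon must be > 0")
        if self.tau_codon < 0:
            raise ValueError("tau_codon must be >= 0")


#: reference wild-type codon kinetics
WT_REFERENCE = VariantSpec("WT", 0.4e-3, 0.1)


def build_translation_network(
    params: TranslationParameters, variant: VariantSpec
) -> ReactionNetwork:
    """Instantiate the five-reaction network for one variant."""
    species = [
        Species("Rib", params.rib0),
        Species("mRNA1", params.mrna1_0),
        Species("mRNA2", params.mrna2_0),
        Species("tRNA", params.trna0),
        Species("Prot", params.prot0),
        Species(_C1, 0),
        Species(_C2, 0),
        Species(_C3, 0),
    ]
    reactions = [
        Reaction(
            ("Rib", "mRNA1"),
            (DelayedProduct(_C1, params.tau_p1),),
            params.k_p1,
            name="R1_initiation",
        ),
        Reaction(
            (_C1, "tRNA"),
            (
                DelayedProduct(_C2, variant.tau_codon),
                DelayedProduct("tRNA", variant.tau_codon),
            ),
            variant.k_codon,
            name="R2_codon_decoding",
        ),
        Reaction(
            (_C2, "mRNA2"),
            (DelayedProduct(_C3, params.tau_p2),),
            params.k_p1,
            name="R3_downstream",
        ),
        Reaction(
            (_C3,),
            (
                DelayedProduct("mRNA1", params.tau_mRNA),
                DelayedProduct("mRNA2", params.tau_mRNA),
                DelayedProduct("Rib", params.tau_Rib),
                DelayedProduct("Prot", params.tau_prot),
            ),
            params.k_release,
            name="R4_release",
        ),
        Reaction(("Prot",), (), params.k_P_decay, name="R5_decay"),
    ]
    return ReactionNetwork(species, reactions)


def simulate_variant(
    params: TranslationParameters,
    variant: VariantSpec,
    seed,
    t_end: float = 3e4,
    sample_interval: float = 10.0,
) -> Trajectory:
    """One realisation of the translation model for one variant."""
    return simulate(
        build_translation_network(params, variant),
        t_end=t_end,
        sample_interval=sample_interval,
        seed=seed,
    )


def time_weighted_mean(
    times: np.ndarray, values: np.ndarray, start: float, end: float
) -> float:
    """Time average of a piecewise-constant, right-continuous series on (start, end]."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    seg_start = np.maximum(times, start)
    seg_end = np.minimum(np.append(times[1:], end), end)
    w = np.clip(seg_end - seg_start, 0.0, None)
    total = w.sum()
    if total <= 0:
        raise ValueError("averaging window is empty")
    return float((values * w).sum() / total)


def posttransient_mean_protein(
    traj: Trajectory, transient_cutoff: float = 1e4
) -> float:
    """Time-averaged protein copy number after the transient.

    The first ``transient_cutoff`` seconds are discarded so the average is
    taken over the stationary fluctuations only.
    """
    t_end = float(traj.times[-1])
    if t_end <= transient_cutoff:
        raise ValueError(
            f"trajectory ends at {t_end} s, inside the transient window "
            f"(cutoff {transient_cutoff} s)"
        )
    return time_weighted_mean(traj.times, traj.series("Prot"), transient_cutoff, t_end)


@dataclass(frozen=True)
class ReplicateSummary:
    """Summary over independent realisations of one parameter set."""

    replicate_means: np.ndarray  # post-transient mean protein per replicate
    n_replicates: int
    transient_cutoff: float
    t_end: float

    @property
    def mean(self) -> float:
        return float(np.mean(self.replicate_means))

    @property
    def sd(self) -> float:
        if self.n_replicates < 2:
            return float("nan")
        return float(np.std(self.replicate_means, ddof=1))

    @property
    def sem(self) -> float:
        return self.sd / np.sqrt(self.n_replicates)


def _replicate_seed(master_seed: int, stream: int, replicate: int):
    # disjoint, reproducible streams per (parameter set, replicate)
    return np.random.SeedSequence((int(master_seed), int(stream), int(replicate)))


def run_replicates(
    params: TranslationParameters,
    variant: VariantSpec,
    n: int = 50,
    master_seed: int = 0,
    t_end: float = 3e4,
    transient_cutoff: float = 1e4,
    sample_interval: float = 10.0,
    stream: int = 0,
) -> ReplicateSummary:
    """Run ``n`` independent realisations and summarise the plateau protein level.

    Replicate seeds derive from ``(master_seed, stream, replicate_index)``;
    distinct ``stream`` values give statistically independent parameter sets
    under one master seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    means = np.empty(n)
    for i in range(n):
        traj = simulate_variant(
            params,
            variant,
            seed=_replicate_seed(master_seed, stream, i),
            t_end=t_end,
            sample_interval=sample_interval,
        )
        means[i] = posttransient_mean_protein(traj, transient_cutoff)
    return ReplicateSummary(
        replicate_means=means,
        n_replicates=n,
        transient_cutoff=transient_cutoff,
        t_end=t_end,
    )


@dataclass
class SweepResult:
    """Ratio surface over the (codon rate, codon delay) grid.

    ``table`` has one row per grid cell with columns ``k_snp``, ``tau_snp``,
    ``mean``, ``sd``, ``n``, ``ratio``, ``ratio_se``; ``wt`` is the shared
    wild-type reference summary.
    """

    table: pd.DataFrame
    wt: ReplicateSummary
    wt_variant: VariantSpec


def sweep_ratio(
    params: TranslationParameters,
    k_values: Sequence[float] = K_SNP_GRID,
    tau_values: Sequence[float] = TAU_SNP_GRID,
    n: int = 50,
    master_seed: int = 0,
    t_end: float = 3e4,
    transient_cutoff: float = 1e4,
    sample_interval: float = 10.0,
    wt: VariantSpec = WT_REFERENCE,
) -> SweepResult:
    """Sweep SNP codon kinetics and report the plateau-protein ratio to WT.

    The WT reference is simulated once (stream 0) and shared by all cells;
    cell ``j`` uses stream ``j + 1`` so all runs are independent.  The ratio
    standard error combines both Monte-Carlo errors in quadrature.
    """
    if len(k_values) == 0 or len(tau_values) == 0:
        raise ValueError("sweep grid must be non-empty")
    wt_summary = run_replicates(
        params, wt, n=n, master_seed=master_seed, t_end=t_end,
        transient_cutoff=transient_cutoff, sample_interval=sample_interval,
        stream=0,
    )
    rows = []
    stream = 1
    for k_snp in k_values:
        for tau_snp in tau_values:
            cell = run_replicates(
                params,
                VariantSpec("SNP", k_snp, tau_snp),
                n=n,
                master_seed=master_seed,
                t_end=t_end,
                transient_cutoff=transient_cutoff,
                sample_interval=sample_interval,
                stream=stream,
            )
            ratio = cell.mean / wt_summary.mean
            ratio_se = ratio * np.hypot(
                cell.sem / cell.mean, wt_summary.sem / wt_summary.mean
            )
            rows.append(
                {
                    "k_snp": k_snp,
                    "tau_snp": tau_snp,
                    "mean": cell.mean,
                    "sd": cell.sd,
                    "n": n,
                    "ratio": ratio,
                    "ratio_se": ratio_se,
                }
            )
            stream += 1
    return SweepResult(table=pd.DataFrame(rows), wt=wt_summary, wt_variant=wt)


# -- conservation accounting ----------------------------------------------------

# which species carry each conserved molecule (free pool listed first)
_CARRIERS = {
    "Rib": ("Rib", _C1, _C2, _C3),
    "mRNA1": ("mRNA1", _C1, _C2, _C3),
    "mRNA2": ("mRNA2", _C3),
    "tRNA": ("tRNA",),
}


def conservation_totals(traj: Trajectory) -> dict[str, np.ndarray]:
    """Total copy number of each conserved molecule at every sample.

    A ribosome is counted whether it is free, inside one of the three
    complexes, or scheduled on the waitlist (as a pending complex or pending
    free ribosome); likewise for the mRNA halves and the tRNA.  In a correct
    simulation each series is exactly constant.
    """
    totals = {}
    for pool, carriers in _CARRIERS.items():
        total = np.zeros(len(traj.times), dtype=np.int64)
        for sp in carriers:
            total += traj.series(sp) + traj.pending_series(sp)
        totals[pool] = total
    return totals
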