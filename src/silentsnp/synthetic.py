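"""Synthetic inputs with the statistical structure the analyses assume.

Two kinds of fixtures live here, both first-class and seeded:

* :func:`generate_panel` emulates a mined cell-line drug-response panel —
  per-drug Gaussian AUC distributions, a genotype-linked AUC shift for
  designated drugs, and a planted subpopulation of strongly sensitive SNP
  lines — together with the ground-truth labels, so classification and
  cohort statistics can be validated without any database download.
* :func:`toy_networks` returns tiny reaction networks with closed-form
  stationary behaviour (birth–death, a single delayed conversion, a two-step
  cascade) for validating the stochastic engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ssa import DelayedProduct, Reaction, ReactionNetwork, Species

__all__ = ["PanelSpec", "generate_panel", "ToyNetwork", "toy_networks"]


@dataclass(frozen=True)
class PanelSpec:
    """Recipe for one synthetic drug-response panel.

    ``snp_effect`` shifts the AUC of every SNP-cohort line (heterozygotes
    included, mirroring the dominant-cohort pooling of the analysis) by that
    many baseline standard deviations for the designated effect drugs; a
    negative value means greater sensitivity.  A ``sensitive_fraction`` of
    the SNP-cohort lines is additionally shifted by ``planted_shift`` sd,
    deep into the sensitive tail; these are the ground-truth positives.

    The planted subpopulation must end up below the Z = -1.5 cutoff *after*
    standardisation against the whole panel, whose standard deviation the
    planted tail itself inflates; a small ``sensitive_fraction`` with a deep
    ``planted_shift`` keeps that margin several noise-sd wide (see the
    methods note for the closed-form margin calculation behind the
    defaults).
    """

    n_wt: int = 40
    n_het: int = 20
    n_snp: int = 10
    drugs: tuple[str, ...] = ("olaparib", "veliparib")
    effect_drugs: tuple[str, ...] = ("olaparib",)
    baseline_auc_mean: float = 0.85
    baseline_auc_sd: float = 0.08
    snp_effect: float = -1.0
    sensitive_fraction: float = 0.1
    planted_shift: float = -5.0
    heavy_tails: bool = False  # Student-t (df=3) noise for robustness checks
    dataset: str = "SYNTH"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_wt, self.n_het, self.n_snp) < 0:
            raise ValueError("cohort sizes must be >= 0")
        if self.n_wt + self.n_het + self.n_snp < 4:
            raise ValueError("panel needs at least 4 cell lines")
        if not self.baseline_auc_sd > 0:
            raise ValueError("baseline_auc_sd must be > 0")
        if not 0 <= self.sensitive_fraction <= 1:
            raise ValueError("sensitive_fraction must be in [0, 1]")
        if not self.drugs:
            raise ValueError("at least one drug is required")
        unknown = set(self.effect_drugs) - set(self.drugs)
        if unknown:
            raise ValueError(f"effect_drugs not in drugs: {sorted(unknown)}")


def generate_panel(spec: PanelSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one panel and its ground truth, reproducibly from ``spec.seed``.

    Returns ``(panel, truth)``: the panel has one row per (cell line, drug)
    with columns ``cell_line, genotype, drug, auc, dataset``; the truth has
    one row per cell line with its genotype and whether it was planted as a
    strongly sensitive line.
    """
    rng = np.random.default_rng(spec.seed)
    genotypes = (
        ["WT/WT"] * spec.n_wt + ["WT/SNP"] * spec.n_het + ["SNP/SNP"] * spec.n_snp
    )
    n = len(genotypes)
    cell_lines = [f"CL{i:04d}" for i in range(n)]
    is_snp_cohort = np.array([g != "WT/WT" for g in genotypes])

    planted = np.zeros(n, dtype=bool)
    snp_idx = np.flatnonzero(is_snp_cohort)
    n_planted = int(round(spec.sensitive_fraction * len(snp_idx)))
    if n_planted:
        planted[rng.choice(snp_idx, size=n_planted, replace=False)] = True

    if spec.heavy_tails:
        noise = lambda size: rng.standard_t(df=3, size=size) / np.sqrt(3)  # noqa: E731
    else:
        noise = rng.standard_normal

    frames = []
    for drug in spec.drugs:
        auc = spec.baseline_auc_mean + spec.baseline_auc_sd * noise(n)
        if drug in spec.effect_drugs:
            auc[is_snp_cohort] += spec.snp_effect * spec.baseline_auc_sd
            auc[planted] += spec.planted_shift * spec.baseline_auc_sd
        frames.append(
            pd.DataFrame(
                {
                    "cell_line": cell_lines,
                    "genotype": genotypes,
                    "drug": drug,
                    "auc": auc,
                    "dataset": spec.dataset,
                }
            )
        )
    panel = pd.concat(frames, ignore_index=True)
    truth = pd.DataFrame(
        {
            "cell_line": cell_lines,
            "genotype": genotypes,
            "planted_sensitive": planted,
        }
    )
    return panel, truth


# -- engine validation fixtures -------------------------------------------------


@dataclass(frozen=True)
class ToyNetwork:
    """A small network with known stationary behaviour."""

    name: str
    network: ReactionNetwork
    stationary_mean: dict[str, float] = field(default_factory=dict)
    notes: str = ""


def toy_networks(
    k_birth: float = 10.0, k_death: float = 0.1, delay: float = 5.0
) -> dict[str, ToyNetwork]:
    """Named fixtures with closed-form stationary statistics.

    * ``birth_death``: constant production at ``k_birth`` (via an immutable
      source species held at count 1) and first-order decay at ``k_death``;
      stationary copy number is Poisson with mean ``k_birth / k_death``
      (Fano factor 1).
    * ``delayed_conversion``: a single molecule A converts to B; B appears
      exactly ``delay`` seconds after the one firing.
    * ``cascade``: source → A → B → sink; at stationarity the flux through
      every stage equals the source rate, so mean A = ``k_birth / k_step``
      and mean B = ``k_birth / k_death``.
    """
    src = Species("Source", 1)
    birth_death = ReactionNetwork(
        [src, Species("P", 0)],
        [
            Reaction(("Source",), ("Source", "P"), k_birth, name="birth"),
            Reaction(("P",), (), k_death, name="death"),
        ],
    )
    delayed_conversion = ReactionNetwork(
        [Species("A", 1), Species("B", 0)],
        [Reaction(("A",), (DelayedProduct("B", delay),), 1.0, name="convert")],
    )
    k_step = 1.0
    cascade = ReactionNetwork(
        [src, Species("A", 0), Species("B", 0)],
        [
            Reaction(("Source",), ("Source", "A"), k_birth, name="source"),
            Reaction(("A",), (DelayedProduct("B", delay),), k_step, name="step"),
            Reaction(("B",), (), k_death, name="sink"),
        ],
    )
    return {
        "birth_death": ToyNetwork(
            "birth_death",
            birth_death,
            stationary_mean={"P": k_birth / k_death},
            notes="Poisson stationary law; Fano factor 1",
        ),
        "delayed_conversion": ToyNetwork(
            "delayed_conversion",
            delayed_conversion,
            notes=f"B appears exactly {delay} s after the single firing",
        ),
        "cascade": ToyNetwork(
            "cascade",
            cascade,
            stationary_mean={"A": k_birth / k_step, "B": k_birth / k_death},
            notes="stationary flux through each stage equals the source rate",
        ),
    }
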