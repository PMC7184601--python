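"""Independent deterministic oracles used to validate the stochastic engine.

The flux-balance oracle treats the translation network as a cyclic queueing
system: at stationarity one flux J runs through the four stages of the
ribosome/mRNA cycle, and Little's law converts each fixed delay into a
standing occupancy J * delay.  Solving the pool-conservation and
mass-action-flux equations for J gives the deterministic mean protein level
J / k_P_decay.  This ignores count-count correlations, so the stochastic
mean is only expected to agree within a tolerance band, but it is built from
closed-form balance laws entirely independent of the SSA code path.
"""

from __future__ import annotations

from scipy.optimize import brentq


def flux_balance_protein_mean(params, variant) -> float:
    """Deterministic plateau protein level of the translation model.

    Unknowns are the stationary flux J and the free pools; all follow from J:

    * tRNA:   T  = trna0 - J*tau_codon           (waitlisted tRNA only)
    * C3 = J / k_release                         (R4 flux balance)
    * mRNA2:  M2 = mrna2_0 - C3 - J*(tau_p2 + tau_mRNA)
    * C2 = J / (k_p1 * M2)                       (R3 flux balance)
    * C1 = J / (k_codon * T)                     (R2 flux balance)
    * mRNA1:  M1 = mrna1_0 - C1 - C2 - C3
                   - J*(tau_p1 + tau_codon + tau_p2 + tau_mRNA)
    * Rib:    R  = rib0 - C1 - C2 - C3
                   - J*(tau_p1 + tau_codon + tau_p2 + tau_Rib)

    and J must satisfy the R1 mass-action law J = k_p1 * R * M1.
    """
    p, v = params, variant

    def residual(J: float) -> float:
        T = p.trna0 - J * v.tau_codon
        C3 = J / p.k_release
        M2 = p.mrna2_0 - C3 - J * (p.tau_p2 + p.tau_mRNA)
        if T <= 0 or M2 <= 0:
            return J  # flux impossible: any positive residual ends the bracket
        C2 = J / (p.k_p1 * M2)
        C1 = J / (v.k_codon * T)
        in_transit = p.tau_p1 + v.tau_codon + p.tau_p2
        M1 = p.mrna1_0 - C1 - C2 - C3 - J * (in_transit + p.tau_mRNA)
        R = p.rib0 - C1 - C2 - C3 - J * (in_transit + p.tau_Rib)
        return J - p.k_p1 * max(R, 0.0) * max(M1, 0.0)

    # J is bounded by the pool constraints; residual is negative near 0
    j_hi = min(
        p.trna0 / v.tau_codon if v.tau_codon > 0 else float("inf"),
        p.mrna2_0 / (1.0 / p.k_release + p.tau_p2 + p.tau_mRNA),
    )
    flux = brentq(residual, 1e-12, j_hi, xtol=1e-12)
    return flux / p.k_P_decay
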