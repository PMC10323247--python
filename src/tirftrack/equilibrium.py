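"""Equilibrium competition model for importin inhibition and Ran rescue.

A minimal 1:1 mass-action system describing why a GFP-tagged microtubule-binding
complex (augmin) disappears from the lattice when importins are added and
returns when Ran-GTP is added:

    augmin + importin  <->  augmin·importin     (Kd = kd_aug_imp)
    Ran-GTP + importinβ <-> Ran·importinβ       (Kd = kd_ran_impB)

"importin" is the inhibitory species: importin β alone, or the preformed 1:1
importin α/β heterodimer when both are supplied (importin α alone is
self-inhibited and inert here).  Ran-GTP sequesters the importin-β moiety,
making it unavailable for cargo; the microtubule-competent fraction is the
free-augmin fraction.  Whether Ran actively strips cargo-bound importin or
only sequesters free importin is indistinguishable at equilibrium — both give
the same end state.

Note a hard algebraic bound of any 1:1 competition: since free importin can
never exceed total importin, ``free_aug_fraction >= kd / (kd + imp_total)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = ["EquilibriumState", "solve_competition", "titration"]

_MASS_TOL = 1e-9  # relative mass-conservation tolerance


@dataclass
class EquilibriumState:
    """Totals, dissociation constants and (after solving) species concentrations.

    All concentrations in nM.  ``impB_total`` (or the α/β heterodimer built
    from ``impA_total``/``impB_total``) is the inhibitory importin pool.
    """

    aug_total: float
    impA_total: float = 0.0
    impB_total: float = 0.0
    ran_total: float = 0.0
    kd_aug_imp: float = 13.1
    kd_ran_impB: float = 0.2
    free_aug_fraction: float | None = None
    species: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("aug_total", "impA_total", "impB_total", "ran_total"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0 (got {v})")
        for name in ("kd_aug_imp", "kd_ran_impB"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0 (got {v})")

    @property
    def inhibitor_total(self) -> float:
        """Total inhibitory importin pool (nM): all importin-β-containing species."""
        return self.impB_total


def _residual(i_free: float, a_tot: float, i_tot: float, r_tot: float,
              kd_ai: float, kd_ri: float) -> float:
    """Importin mass balance as a function of free importin.

    i_free + [aug·imp] + [Ran·imp] - i_tot, with the complexes expressed
    through their own (exact) conservation relations; strictly increasing in
    ``i_free``, so a bracketing root solve is safe.
    """
    ai = a_tot * i_free / (kd_ai + i_free)
    ri = r_tot * i_free / (kd_ri + i_free)
    return i_free + ai + ri - i_tot


def solve_competition(state: EquilibriumState, xtol: float = 1e-12) -> EquilibriumState:
    """Solve the coupled 1:1 competition system.

    Returns a new :class:`EquilibriumState` with ``species`` filled in
    (``aug_free``, ``imp_free``, ``ran_free``, ``aug_imp``, ``ran_imp``) and
    ``free_aug_fraction`` set.  Raises ``RuntimeError`` with the residual if
    the bracketing solve fails to converge.
    """
    a_tot = state.aug_total
    i_tot = state.inhibitor_total
    r_tot = state.ran_total
    kd_ai = state.kd_aug_imp
    kd_ri = state.kd_ran_impB

    if i_tot == 0:
        i_free = 0.0
    else:
        lo, hi = 0.0, i_tot
        try:
            i_free = brentq(
                _residual, lo, hi, args=(a_tot, i_tot, r_tot, kd_ai, kd_ri),
                xtol=xtol * max(1.0, i_tot), rtol=8.9e-16, maxiter=200,
            )
        except (ValueError, RuntimeError) as exc:  # pragma: no cover - defensive
            res_lo = _residual(lo, a_tot, i_tot, r_tot, kd_ai, kd_ri)
            res_hi = _residual(hi, a_tot, i_tot, r_tot, kd_ai, kd_ri)
            raise RuntimeError(
                "competition solve failed to converge: "
                f"residual({lo})={res_lo:.3e}, residual({hi})={res_hi:.3e}"
            ) from exc
        # Newton polish: brentq's x-tolerance is absolute, which leaves a
        # relative residual when free importin is orders of magnitude below
        # the total (steep mass balance); two analytic steps fix that.
        for _ in range(3):
            f = _residual(i_free, a_tot, i_tot, r_tot, kd_ai, kd_ri)
            df = (
                1.0
                + a_tot * kd_ai / (kd_ai + i_free) ** 2
                + r_tot * kd_ri / (kd_ri + i_free) ** 2
            )
            i_free = min(max(i_free - f / df, 0.0), i_tot)

    ai = a_tot * i_free / (kd_ai + i_free)
    ri = r_tot * i_free / (kd_ri + i_free)
    a_free = a_tot - ai
    r_free = r_tot - ri
    frac = a_free / a_tot if a_tot > 0 else kd_ai / (kd_ai + i_free)

    resid = abs(_residual(i_free, a_tot, i_tot, r_tot, kd_ai, kd_ri))
    if i_tot > 0 and resid > _MASS_TOL * max(1.0, i_tot):
        raise RuntimeError(f"competition solve residual too large: {resid:.3e} nM")

    out = EquilibriumState(
        aug_total=a_tot, impA_total=state.impA_total, impB_total=state.impB_total,
        ran_total=r_tot, kd_aug_imp=kd_ai, kd_ran_impB=kd_ri,
    )
    out.species = {
        "aug_free": a_free,
        "imp_free": i_free,
        "ran_free": r_free,
        "aug_imp": ai,
        "ran_imp": ri,
    }
    out.free_aug_fraction = frac
    return out


def titration(
    aug_total: float,
    imp_doses: np.ndarray,
    ran_total: float = 0.0,
    kd_aug_imp: float = 13.1,
    kd_ran_impB: float = 0.2,
) -> np.ndarray:
    """Free-augmin fraction across an importin dose series (vector helper)."""
    out = []
    for dose in np.asarray(imp_doses, dtype=float):
        st = solve_competition(
            EquilibriumState(
                aug_total=aug_total, impB_total=float(dose), ran_total=ran_total,
                kd_aug_imp=kd_aug_imp, kd_ran_impB=kd_ran_impB,
            )
        )
        out.append(st.free_aug_fraction)
    return np.array(out)
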