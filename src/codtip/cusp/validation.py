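"""Four-criterion validation protocol for a fitted cusp model.

(i)   the state variable must load significantly on the canonical state
      (Wald test on omega1 at 5%);
(ii)  canonical states of bistable-classified years should show bimodality
      (dip test; needs >= 10 such years to be assessable);
(iii) the share of observations inside the cusp area;
(iv)  goodness of fit: Cobb pseudo-R^2 plus the AIC comparison against the
      linear and logistic alternatives.

Verdict "valid" requires (i) to pass, the cusp AIC to be the lowest of the
three models, and a nonzero share of observations in the cusp area.  AIC
comparability between a state-density likelihood and least-squares
alternatives is conventional rather than exact; the report carries a caveat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..data_model import ValidationError
from ._dip import dip_pvalue
from .alternatives import AlternativeFits
from .fitting import CuspFit, pseudo_r2

AIC_CAVEAT = ("AIC comparison between the cusp state-density likelihood and "
              "Gaussian least-squares alternatives follows the conventional "
              "practice for this model family and should be read as indicative.")


@dataclass(frozen=True)
class CuspValidationReport:
    omega1_significant: bool
    p_omega1: float
    bimodality_assessable: bool
    bimodality_in_cusp: bool | None
    dip_statistic: float | None
    dip_pvalue: float | None
    pct_in_cusp: float
    pseudo_r2: float
    aic_cusp: float
    aic_linear: float
    aic_logistic: float | None
    verdict: str
    caveat: str = AIC_CAVEAT

    def to_dict(self) -> dict:
        return {
            "omega1_significant": self.omega1_significant,
            "p_omega1": self.p_omega1,
            "bimodality": {
                "assessable": self.bimodality_assessable,
                "bimodal": self.bimodality_in_cusp,
                "dip": self.dip_statistic,
                "p_value": self.dip_pvalue,
            },
            "pct_in_cusp": self.pct_in_cusp,
            "pseudo_r2": self.pseudo_r2,
            "aic": {"cusp": self.aic_cusp, "linear": self.aic_linear,
                    "logistic": self.aic_logistic},
            "verdict": self.verdict,
            "caveat": self.caveat,
        }


def validate_cusp(
    fit: CuspFit,
    alternatives: AlternativeFits,
    alpha_level: float = 0.05,
    dip_boot: int = 200,
    seed: int = 12345,
) -> CuspValidationReport:
    """Apply the four validation criteria to a converged cusp fit."""
    if not fit.converged:
        raise ValidationError("validation requires a converged cusp fit")

    p_w1 = fit.p_omega1
    crit_i = bool(np.isfinite(p_w1) and p_w1 < alpha_level)

    z_bistable = np.array(
        [p.z for p in fit.per_year if p.state_class == "bistable"])
    if len(z_bistable) >= 10:
        dip, p_dip = dip_pvalue(z_bistable, n_boot=dip_boot, seed=seed)
        assessable, bimodal = True, bool(p_dip < alpha_level)
    else:
        dip, p_dip, assessable, bimodal = None, None, False, None

    pct = fit.pct_in_cusp
    r2 = pseudo_r2(fit, "nearest_mode")

    aics = [fit.aic, alternatives.aic_linear]
    if alternatives.aic_logistic is not None:
        aics.append(alternatives.aic_logistic)
    cusp_best = fit.aic <= min(aics)

    verdict = "valid" if (crit_i and cusp_best and pct > 0) else "not valid"
    return CuspValidationReport(
        omega1_significant=crit_i,
        p_omega1=float(p_w1),
        bimodality_assessable=assessable,
        bimodality_in_cusp=bimodal,
        dip_statistic=dip,
        dip_pvalue=p_dip,
        pct_in_cusp=float(pct),
        pseudo_r2=float(r2),
        aic_cusp=float(fit.aic),
        aic_linear=float(alternatives.aic_linear),
        aic_logistic=alternatives.aic_logistic,
        verdict=verdict,
    )
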