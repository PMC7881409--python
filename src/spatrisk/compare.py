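"""DIC-based model comparison.

DIC = Dbar + pD where Dbar is the posterior mean deviance and
pD = Dbar - Dhat the effective number of parameters, Dhat being the
deviance at the posterior mean of each area's log-linear predictor (not at
the posterior means of individual parameters — the u/delta split is not
identified area by area, but their sum is). Both the raw deviance
(-2 log L) and the saturated-deviance convention are available, labelled
explicitly, because published tables do not always say which they used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .bym import PosteriorSample
from .data import ValidationError
from .glm import minus2loglik_poisson, saturated_deviance_poisson


@dataclass
class DicReport:
    label: str
    dbar: float
    dhat: float
    p_d: float
    dic: float
    minus2loglik: float
    convention: str  # "raw" | "saturated"

    def __post_init__(self) -> None:
        if self.convention not in ("raw", "saturated"):
            raise ValidationError(f"unknown deviance convention {self.convention!r}")
        if not np.isfinite(self.p_d):
            raise ValidationError("p_d must be finite")
        if self.p_d < 0:
            import logging

            logging.getLogger(__name__).warning(
                "negative effective parameter count p_d=%.3f for %s",
                self.p_d,
                self.label,
            )


def dic_from_draws(
    sample: PosteriorSample,
    label: str = "spatial",
    convention: str = "raw",
    burn_in: int | None = None,
    thin: int | None = None,
) -> DicReport:
    """DIC from stored per-draw deviances of a posterior sample."""
    sl = sample.retained(burn_in, thin)
    dev = sample.deviance_raw[sl] if convention == "raw" else sample.deviance_sat[sl]
    if dev.size == 0:
        raise ValidationError("no retained draws with stored deviance")
    dbar = float(dev.mean())
    # Dhat at the posterior mean of each area's log relative risk
    eta_bar = np.log(sample.theta[sl]).mean(axis=0)
    mu_hat = sample.expected * np.exp(eta_bar)
    if convention == "raw":
        dhat = minus2loglik_poisson(sample.observed, mu_hat)
    else:
        dhat = saturated_deviance_poisson(sample.observed, mu_hat)
    p_d = dbar - dhat
    return DicReport(
        label=label,
        dbar=dbar,
        dhat=dhat,
        p_d=p_d,
        dic=dbar + p_d,
        minus2loglik=dbar,
        convention=convention,
    )


def dic_report_from_glm(fit, label: str = "non-spatial") -> DicReport:
    """Plug-in DIC report for a maximum-likelihood GLM fit.

    For a point fit, Dbar = Dhat = -2loglik at the MLE and pD is taken as
    the free-parameter count, giving DIC = -2loglik + 2p.
    """
    from .glm import glm_dic

    dic, m2ll = glm_dic(fit)
    p = float(fit.n_params)
    return DicReport(
        label=label,
        dbar=m2ll + p,  # so that dic = dbar + p_d with p_d = p
        dhat=m2ll,
        p_d=p,
        dic=dic,
        minus2loglik=m2ll,
        convention="raw",
    )


def compare_models(reports: Sequence[DicReport]) -> pd.DataFrame:
    """Rank models by DIC, ascending; differences < 5 flagged not decisive."""
    if len(reports) < 2:
        raise ValidationError("need >= 2 reports to compare")
    conventions = {r.convention for r in reports}
    if len(conventions) > 1:
        raise ValidationError(
            f"mixed deviance conventions {sorted(conventions)}; refuse to compare"
        )
    order = sorted(range(len(reports)), key=lambda k: (reports[k].dic, k))
    best = reports[order[0]].dic
    rows = []
    for rank, k in enumerate(order, start=1):
        r = reports[k]
        rows.append(
            {
                "rank": rank,
                "model": r.label,
                "dic": r.dic,
                "p_d": r.p_d,
                "minus2loglik": r.minus2loglik,
                "delta_dic": r.dic - best,
                "decisive": bool(r.dic - best >= 5.0) if rank > 1 else False,
            }
        )
    return pd.DataFrame(rows)
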