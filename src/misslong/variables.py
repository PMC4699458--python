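"""Variable definitions for the longitudinal infant-immunology cohort.

Each measured quantity is described by a :class:`VariableSpec`: its scale
(bounded percentage, positive continuous, detection-limited concentration,
or log10 copies), the assay panel it travels with (a failed blood draw
removes a whole panel at once), and per-(group, visit) target means and
standard deviations.

The default catalogue mirrors a two-arm infant ART cohort with an
HIV-exposed-uninfected (HEU) control group: 17 measurement columns
(birth weight, CD4%, 12 flow-cytometry percentages, CD38 MFI, serum IL-7,
and log10 viral load).  Group labels are ``ART-Def`` (deferred treatment),
``ART-Early`` (treatment at enrollment) and ``HEU`` (single-visit
controls, no viral load).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

GROUPS = ("ART-Def", "ART-Early", "HEU")
PANELS = ("core", "cd4", "flow", "elisa", "vl")
SCALES = ("percent", "positive", "pg_per_ml", "log10_copies")

#: tiny offset keeping percentage draws strictly inside (0, 100)
_EDGE = 1e-6


@dataclass(frozen=True)
class VariableSpec:
    """Scale, panel and calibration targets for one measured variable.

    Parameters
    ----------
    name : str
        Column label.
    scale : str
        One of ``percent`` (bounded [0, 100]), ``positive`` (MFI, grams),
        ``pg_per_ml`` (ELISA with detection range, censored at the limits)
        or ``log10_copies``.
    panel : str
        Assay panel: ``core``, ``cd4``, ``flow``, ``elisa`` or ``vl``.
    moments : dict
        ``(group, visit) -> (mean, sd)`` calibration targets.  Cells absent
        from the dict are structurally unmeasured (e.g. viral load in HEU).
    bounds : tuple
        ``(lower, upper)``; draws never leave this interval.
    censored : bool
        If True the bounds are detection limits (values pile up at the
        limit); otherwise the distribution is truncated at the bounds.
    corr_group : str or None
        Variables sharing a label are drawn with exchangeable latent
        correlation; ``None`` means independent of everything else.
    """

    name: str
    scale: str
    panel: str
    moments: dict = field(default_factory=dict)
    bounds: tuple = (-np.inf, np.inf)
    censored: bool = False
    corr_group: str | None = None

    def __post_init__(self):
        if self.scale not in SCALES:
            raise ValueError(f"{self.name}: unknown scale {self.scale!r}")
        if self.panel not in PANELS:
            raise ValueError(f"{self.name}: unknown panel {self.panel!r}")
        lo, hi = self.bounds
        if not lo < hi:
            raise ValueError(f"{self.name}: bounds must be ordered, got {self.bounds}")
        for key, (m, s) in self.moments.items():
            if not s > 0:
                raise ValueError(f"{self.name}{key}: SD must be > 0, got {s}")
            if not lo <= m <= hi:
                raise ValueError(
                    f"infeasible spec for variable {self.name!r} at {key}: "
                    f"mean {m} outside bounds {self.bounds}"
                )


def _truncnorm_moments(mu, sigma, lo, hi):
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
    return float(m), float(np.sqrt(v))


def _censored_moments(mu, sigma, lo, hi):
    # Y = clip(X, lo, hi) with X ~ N(mu, sigma^2): closed-form mixed moments.
    al, be = (lo - mu) / sigma, (hi - mu) / sigma
    Fl, Fu = stats.norm.cdf(al), stats.norm.cdf(be)
    fl, fu = stats.norm.pdf(al), stats.norm.pdf(be)
    pmid = Fu - Fl
    m_mid = mu * pmid - sigma * (fu - fl)
    e1 = lo * Fl + hi * (1.0 - Fu) + m_mid
    # E[X^2; al<Z<be] = (mu^2+sigma^2)P - sigma^2(be*fu - al*fl) - 2 mu sigma (fu - fl)
    e2_mid = (mu**2 + sigma**2) * pmid - sigma**2 * (be * fu - al * fl) - 2 * mu * sigma * (fu - fl)
    e2 = lo**2 * Fl + hi**2 * (1.0 - Fu) + e2_mid
    var = max(e2 - e1**2, 0.0)
    return float(e1), float(np.sqrt(var))


from functools import lru_cache


@lru_cache(maxsize=4096)
def match_latent_params(mean, sd, bounds, censored=False):
    """Latent (mu, sigma) whose truncated/censored normal has the target moments.

    With bounds far away this is the identity.  The mean is always matched
    exactly (it is monotone in mu at fixed sigma); the SD is matched by an
    outer 1-D solve in sigma.  For targets whose SD is not attainable under
    truncation (the truncated-normal coefficient of variation near a bound
    is capped), sigma is capped and the SD is the closest achievable.
    """
    lo, hi = bounds
    if sd <= 1e-8 or (np.isinf(lo) and np.isinf(hi)):
        return float(mean), float(max(sd, 1e-12))
    # negligible out-of-bounds mass: no adjustment needed
    tail = stats.norm.cdf(lo, mean, sd) + stats.norm.sf(hi, mean, sd)
    if tail < 1e-10:
        return float(mean), float(sd)
    momf = _censored_moments if censored else _truncnorm_moments

    def mu_for(sigma):
        # bounded-distribution mean sweeps (lo, hi) as mu runs over the line
        a = (lo if np.isfinite(lo) else mean) - 60 * sigma
        b = (hi if np.isfinite(hi) else mean) + 60 * sigma
        return optimize.brentq(lambda mu: momf(mu, sigma, lo, hi)[0] - mean, a, b,
                               xtol=1e-10 * max(1.0, abs(mean)))

    def sd_at(sigma):
        # None when the mean target is unreachable at this sigma (the
        # achievable-mean range collapses toward the midpoint as sigma grows)
        try:
            return momf(mu_for(sigma), sigma, lo, hi)[1]
        except ValueError:
            return None

    # scan a log-sigma grid for a bracket around the SD target
    grid = np.log(sd) + np.arange(-4.0, 8.01, 0.5)
    best_sigma, best_gap = float(sd), np.inf
    prev = None  # (log_sigma, err)
    sigma = None
    for ls in grid:
        s = float(np.exp(ls))
        val = sd_at(s)
        if val is None:
            break
        err = val - sd
        if abs(err) < best_gap:
            best_sigma, best_gap = s, abs(err)
        if prev is not None and prev[1] < 0 <= err:
            sigma = float(np.exp(optimize.brentq(
                lambda l: sd_at(float(np.exp(l))) - sd, prev[0], ls, xtol=1e-10)))
            break
        prev = (ls, err)
    if sigma is None:
        sigma = best_sigma  # SD unattainable: closest achievable
    return float(mu_for(sigma)), sigma


def sample_bounded(z, mean, sd, bounds, censored=False):
    """Map standard-normal draws ``z`` to bounded values with the target moments."""
    mu, sigma = match_latent_params(mean, sd, bounds, censored=censored)
    lo, hi = bounds
    if censored:
        return np.clip(mu + sigma * z, lo, hi)
    if np.isinf(lo) and np.isinf(hi):
        return mu + sigma * z
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    u = stats.norm.cdf(z)
    x = stats.truncnorm.ppf(u, a, b, loc=mu, scale=sigma)
    # keep strictly inside open bounds (percentages never reach 0 or 100)
    return np.clip(x, lo + _EDGE * max(1.0, abs(lo)), hi - _EDGE * max(1.0, abs(hi)))


def _m(def1, early1, def2, early2, heu=None):
    out = {
        ("ART-Def", 1): def1,
        ("ART-Early", 1): early1,
        ("ART-Def", 2): def2,
        ("ART-Early", 2): early2,
    }
    if heu is not None:
        out[("HEU", 1)] = heu
    return out


def default_variables() -> list[VariableSpec]:
    """The 17-variable catalogue with published per-(group, visit) moments."""
    pct = dict(scale="percent", panel="flow", bounds=(0.0, 100.0))
    tc = dict(corr_group="tcell")
    return [
        VariableSpec("birth_weight_g", "positive", "core", bounds=(300.0, 6000.0),
                     moments=_m((2962.9, 551.7), (2930.2, 396.3), (2727.1, 390.4),
                                (2895.5, 405.9), (2573.0, 703.0))),
        VariableSpec("cd4_pct", "percent", "cd4", bounds=(0.0, 100.0), **tc,
                     moments=_m((32.9, 7.9), (37.7, 8.4), (34.5, 7.6),
                                (37.9, 6.0), (42.5, 6.8))),
        VariableSpec("cd38_pct_cd8", **pct, **tc,
                     moments=_m((99.1, 0.8), (97.6, 2.0), (97.8, 3.8),
                                (97.7, 2.5), (97.8, 2.2))),
        VariableSpec("hladr_pct_cd8", **pct, **tc,
                     moments=_m((38.0, 17.6), (10.9, 8.8), (22.9, 19.7),
                                (21.9, 16.7), (8.0, 8.8))),
        VariableSpec("cd95_pct_cd8", **pct, **tc,
                     moments=_m((93.4, 7.7), (67.7, 27.5), (87.0, 11.5),
                                (73.4, 22.3), (84.3, 19.4))),
        VariableSpec("nk_mature_pct", **pct,
                     moments=_m((55.4, 16.5), (52.4, 16.5), (62.4, 7.7),
                                (60.7, 16.9), (60.3, 15.7))),
        VariableSpec("nk_immature_pct", **pct,
                     moments=_m((3.1, 3.4), (5.4, 5.4), (2.8, 1.9),
                                (4.4, 5.8), (3.2, 2.3))),
        VariableSpec("pdc_pct", **pct,
                     moments=_m((0.3, 0.1), (0.3, 0.2), (0.4, 0.7),
                                (0.4, 0.4), (0.2, 0.3))),
        VariableSpec("cd28_naive_cd4_pct", **pct, **tc,
                     moments=_m((76.1, 9.5), (75.7, 8.7), (69.7, 7.4),
                                (70.3, 11.3), (67.4, 10.2))),
        VariableSpec("cd27_naive_cd4_pct", **pct, **tc,
                     moments=_m((80.5, 8.5), (83.6, 9.3), (78.4, 10.4),
                                (80.7, 5.7), (74.8, 11.3))),
        VariableSpec("cd28_naive_cd8_pct", **pct, **tc,
                     moments=_m((40.8, 20.5), (56.7, 18.7), (36.7, 18.7),
                                (49.6, 18.4), (51.4, 18.1))),
        VariableSpec("cd27_naive_cd8_pct", **pct, **tc,
                     moments=_m((53.7, 18.1), (74.5, 16.8), (54.5, 16.2),
                                (67.8, 14.2), (76.8, 12.7))),
        VariableSpec("cm_cd4_pct", **pct, **tc,
                     moments=_m((19.7, 8.3), (21.1, 8.7), (17.7, 11.2),
                                (22.6, 8.4), (22.7, 8.0))),
        VariableSpec("cm_cd8_pct", **pct, **tc,
                     moments=_m((22.9, 12.5), (11.8, 5.7), (20.9, 4.0),
                                (16.9, 6.1), (13.0, 5.2))),
        VariableSpec("cd38_mfi", "positive", "flow", bounds=(1.0, 20000.0), **tc,
                     moments=_m((1402.0, 790.9), (551.8, 230.5), (658.6, 390.8),
                                (830.6, 355.9), (526.9, 278.2))),
        VariableSpec("il7_pg_ml", "pg_per_ml", "elisa", bounds=(0.25, 16.0),
                     censored=True,
                     moments=_m((4.1, 3.7), (5.4, 4.4), (4.0, 3.6),
                                (4.9, 3.4), (2.4, 1.9))),
        VariableSpec("log10_vl", "log10_copies", "vl", bounds=(0.0, 9.0),
                     moments=_m((5.9, 0.8), (3.1, 0.6), (5.0, 1.6), (3.0, 1.0))),
    ]


#: the responses analysed in the arm-effect models (viral load and birth
#: weight are covariates/descriptors, not modelled responses)
RESPONSE_VARIABLES = [
    "cd4_pct", "cd38_pct_cd8", "hladr_pct_cd8", "cd95_pct_cd8",
    "nk_mature_pct", "nk_immature_pct", "pdc_pct",
    "cd28_naive_cd4_pct", "cd27_naive_cd4_pct",
    "cd28_naive_cd8_pct", "cd27_naive_cd8_pct",
    "cm_cd4_pct", "cm_cd8_pct", "cd38_mfi", "il7_pg_ml",
]
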