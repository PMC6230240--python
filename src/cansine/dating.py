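"""Subfamily age estimation from CpG/non-CpG divergence and relative
activity chronologies from nested (transposition-in-transposition)
insertions.

Ages use the two substitution rates of the caniform genomes — 0.0013
substitutions/site/My at ordinary sites and 0.0104 at hypermutable CpG
sites — with a saturation guard: age = -ln(1 - d)/r per mutation class,
averaged over the two classes. CpG divergences above ~0.1 are materially
non-linear, so the logarithmic form matters there; for small d it reduces
to d/r.

The TinT model: old inactive families cannot insert into young families.
Each family's insertion times are modelled as a Gaussian on an arbitrary
(relative) timescale and the expected count of family g nested inside
family f is k * a_f * a_g * P(T_g > T_f), larger T meaning more recent.
The Gaussians are fitted by maximising the Poisson likelihood of the
observed count matrix.
"""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

from .io import RepeatAnnotation


# ---------------------------------------------------------------------------
# CpG-aware age estimation
# ---------------------------------------------------------------------------

@dataclass
class AgeConfig:
    rate_non_cpg: float = 0.0013      # substitutions / site / My
    rate_cpg: float = 0.0104
    exclude_ct_microsatellite: bool = False
    calibration_my: float = 15.5      # panda-polar bear split, metadata only

    def __post_init__(self) -> None:
        if self.rate_non_cpg <= 0 or self.rate_cpg <= 0:
            raise ValueError("rates must be > 0")


@dataclass
class AgeEstimate:
    age_non_cpg_my: float
    age_cpg_my: float
    age_mean_my: float
    n_elements: int = 1
    divergence_non_cpg: float = 0.0
    divergence_cpg: float = 0.0


def estimate_age_cpg(divergence_cpg: float, divergence_non_cpg: float,
                     config: AgeConfig | None = None,
                     n_elements: int = 1) -> AgeEstimate:
    """Age from class-stratified divergences: -ln(1-d)/r per class, averaged.

    Divergences must lie in [0, 1)."""
    config = config or AgeConfig()
    for d in (divergence_cpg, divergence_non_cpg):
        if not 0.0 <= d < 1.0:
            raise ValueError(f"divergence {d} outside [0, 1)")
    age_cpg = -math.log1p(-divergence_cpg) / config.rate_cpg
    age_non = -math.log1p(-divergence_non_cpg) / config.rate_non_cpg
    return AgeEstimate(age_non, age_cpg, 0.5 * (age_cpg + age_non),
                       n_elements, divergence_non_cpg, divergence_cpg)


def pooled_age_estimate(divergences, config: AgeConfig | None = None
                        ) -> AgeEstimate:
    """Pool per-element divergence counts across a cohort and date the pool.

    ``divergences`` is an iterable of DivergenceEstimate (raw mode); counts
    are summed so short elements do not dominate."""
    mis_cpg = mat_cpg = mis_non = mat_non = 0
    n = 0
    for d in divergences:
        c = d.counts
        mis_cpg += c["mismatched_cpg"]
        mat_cpg += c["matched_cpg"]
        mis_non += c["mismatched"] - c["mismatched_cpg"]
        mat_non += c["matched"] - c["matched_cpg"]
        n += 1
    d_cpg = mis_cpg / (mis_cpg + mat_cpg) if (mis_cpg + mat_cpg) else 0.0
    d_non = mis_non / (mis_non + mat_non) if (mis_non + mat_non) else 0.0
    return estimate_age_cpg(d_cpg, d_non, config, n_elements=n)


# ---------------------------------------------------------------------------
# nested insertion detection
# ---------------------------------------------------------------------------

@dataclass
class TinTMatrix:
    counts: pd.DataFrame              # rows outer family, columns inner
    abundances: dict[str, int]
    skipped: int = 0

    @property
    def families(self) -> list[str]:
        return list(self.counts.index)


def detect_nested_insertions(annotations: list[RepeatAnnotation],
                             min_extension: int = 4,
                             collinear_slack: int = 10) -> TinTMatrix:
    """Count family-into-family nestings from fragment structure.

    A nesting is scored when consecutive fragments of a multi-fragment
    element sandwich one or more *complete* annotations of another element;
    each outer fragment adjacent to the interruption must span at least
    ``min_extension`` bp and the outer fragments' consensus coordinates
    must be collinear (increasing along the genome on '+', decreasing on
    '-', within ``collinear_slack``). Only immediate nestings count: an
    inner element contained in another element inside the same gap is
    attributed to that inner container when its own fragments are scanned.
    """
    families = sorted({a.family for a in annotations})
    counts = pd.DataFrame(0, index=families, columns=families, dtype=int)
    abundances = {f: 0 for f in families}
    skipped = 0

    by_scaffold: dict[str, list[RepeatAnnotation]] = {}
    for ann in annotations:
        abundances[ann.family] += 1
        by_scaffold.setdefault(ann.scaffold, []).append(ann)

    for scaffold, anns in by_scaffold.items():
        anns = sorted(anns, key=lambda a: (a.start, a.end, str(a.element_id)))
        starts = [a.start for a in anns]
        for outer in anns:
            if len(outer.fragments) < 2:
                continue
            for f1, f2 in zip(outer.fragments, outer.fragments[1:]):
                gap = (f1.end, f2.start)
                if gap[1] <= gap[0]:
                    continue
                if len(f1) < min_extension or len(f2) < min_extension:
                    skipped += 1
                    continue
                if not _collinear(f1, f2, outer.strand, collinear_slack):
                    skipped += 1
                    continue
                inside = []
                lo = bisect_left(starts, gap[0])
                hi = bisect_right(starts, gap[1])
                for cand in anns[lo:hi]:
                    if cand is outer:
                        continue
                    if cand.start >= gap[0] and cand.end <= gap[1]:
                        inside.append(cand)
                for inner in inside:
                    contained = any(inner is not o and inner.start >= o.start
                                    and inner.end <= o.end for o in inside)
                    if not contained:
                        counts.loc[outer.family, inner.family] += 1
    return TinTMatrix(counts, abundances, skipped)


def _collinear(f1, f2, strand: str, slack: int) -> bool:
    if strand == "+":
        return f2.cons_start >= f1.cons_end - slack
    return f1.cons_start >= f2.cons_end - slack


# ---------------------------------------------------------------------------
# activity-period fitting
# ---------------------------------------------------------------------------

@dataclass
class ActivityEstimate:
    family: str
    mu: float                        # peak activity on the relative timescale
    sigma: float
    p75: tuple[float, float]
    p99: tuple[float, float]
    log_likelihood: float = 0.0


_Z75 = norm.ppf(0.875)               # central 75% interval half-width
_Z99 = norm.ppf(0.995)


def estimate_activity_periods(tint: TinTMatrix, seed: int = 0,
                              n_starts: int = 8) -> list[ActivityEstimate]:
    """Fit Gaussian activity curves to a nesting count matrix.

    The timescale runs old -> young (larger mu = more recently active); it
    is gauge-fixed to mean 0, variance 1 across families. Raises when the
    matrix carries no nesting signal at all.
    """
    families = tint.families
    F = len(families)
    if F < 2:
        raise ValueError("need at least two families")
    N = tint.counts.to_numpy(dtype=float)
    if N.sum() == 0:
        raise ValueError("no nesting signal")
    a = np.array([max(tint.abundances.get(f, 1), 1) for f in families],
                 dtype=float)
    a = a / a.mean()

    def unpack(x):
        mu = x[:F]
        # clip log-sigma: keeps the objective finite when a line search
        # wanders, without constraining any realistic optimum
        sigma = np.exp(np.clip(x[F:2 * F], -8.0, 8.0))
        k = math.exp(min(x[-1], 30.0))
        return mu, sigma, k

    def nll(x):
        mu, sigma, k = unpack(x)
        s2 = sigma[:, None] ** 2 + sigma[None, :] ** 2
        z = (mu[None, :] - mu[:, None]) / np.sqrt(s2)
        p = norm.cdf(z)
        lam = k * np.outer(a, a) * p + 1e-12
        return float(np.sum(lam - N * np.log(lam)))

    rng = np.random.default_rng(seed)
    total = N.sum()
    best_x, best_val = None, math.inf
    for _ in range(n_starts):
        x0 = np.concatenate([rng.normal(0, 1, F), rng.normal(0, 0.3, F),
                             [math.log(max(total, 1.0) / max(F * F, 1) + 1e-9)]])
        res = minimize(nll, x0, method="L-BFGS-B")
        if res.fun < best_val:
            best_val, best_x = res.fun, res.x

    mu, sigma, _ = unpack(best_x)
    centre, spread = mu.mean(), mu.std()
    if spread > 1e-9:
        mu = (mu - centre) / spread
        sigma = sigma / spread
    else:
        mu = mu - centre
    out = []
    for i, fam in enumerate(families):
        out.append(ActivityEstimate(
            family=fam, mu=float(mu[i]), sigma=float(sigma[i]),
            p75=(float(mu[i] - _Z75 * sigma[i]), float(mu[i] + _Z75 * sigma[i])),
            p99=(float(mu[i] - _Z99 * sigma[i]), float(mu[i] + _Z99 * sigma[i])),
            log_likelihood=-best_val))
    return out


def activity_table(estimates: list[ActivityEstimate]) -> pd.DataFrame:
    return pd.DataFrame([{
        "family": e.family, "mu": e.mu, "sigma": e.sigma,
        "p75_lo": e.p75[0], "p75_hi": e.p75[1],
        "p99_lo": e.p99[0], "p99_hi": e.p99[1],
        "log_likelihood": e.log_likelihood,
    } for e in estimates])
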