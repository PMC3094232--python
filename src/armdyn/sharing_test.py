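"""Monte-Carlo test for nonrandom co-location of homologs in inversion pairs.

Under the null, the N homologs shared by an arm pair are uniformly and
independently positioned on both arms, so the expected count for region pair
(i, j) is E_{i,j} = N f_i f_j, with f the fractional region lengths. The
statistic sums the per-pair discrepancies (O - E)^2 / E over inversion pairs;
its null distribution is approximated both by the asymptotic chi-squared law
and by repositioning every homolog pair uniformly on its two arms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_maps import (ArmdynError, ArmRegionSet, HomologTable, MarkerMap,
                      SharedCountTable, count_shared)

logger = logging.getLogger("armdyn")


@dataclass
class SharingTestResult:
    region_ids1: list[str]
    region_ids2: list[str]
    O: np.ndarray                    # observed counts on the tested scope
    E: np.ndarray                    # expected counts N f_i f_j
    D: np.ndarray                    # (O - E)^2 / E
    sign: np.ndarray                 # sign(O - E), for hot/cold rendering
    statistic: float                 # T = sum D
    df: int
    p_asymptotic: float
    p_simulated: float | None = None
    n_draws: int = 0
    n_exceed: int = 0
    seed: int | None = None
    null_sample: np.ndarray | None = None

    def format_p_simulated(self) -> str:
        if self.p_simulated is None:
            return "NA"
        if self.n_exceed == 0:
            return f"< {1.0 / self.n_draws:g}"
        return f"{self.p_simulated:.4g}"


def expected_counts(table: SharedCountTable, scope: str = "inversions",
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Expected counts E_{i,j} = N f_i f_j on the statistic's scope.

    ``scope`` is "inversions" (inversion x inversion pairs, the tested scope)
    or "all" (includes the outside regions, as in the intensity model).
    Pairs with f = 0 are excluded (mask False) with a logged warning, since D
    would divide by E = 0. Returns (O_scope, E, mask, signs-compatible shape).
    """
    if table.n_homologs <= 0:
        raise ArmdynError("N must be positive")
    if scope == "inversions":
        i1, i2 = table.inversion_index1, table.inversion_index2
    elif scope == "all":
        i1 = np.arange(len(table.region_ids1))
        i2 = np.arange(len(table.region_ids2))
    else:
        raise ArmdynError(f"unknown scope {scope!r}")
    if i1.size == 0 or i2.size == 0:
        raise ArmdynError("no regions in scope on one of the arms")
    f1, f2 = table.f1[i1], table.f2[i2]
    E = table.n_homologs * np.outer(f1, f2)
    mask = E > 0
    if not mask.all():
        logger.warning("excluding %d region pair(s) with zero expected count", (~mask).sum())
    O = table.O[np.ix_(i1, i2)]
    return O, E, mask, (i1, i2)


def sharing_statistic(O: np.ndarray, E: np.ndarray, mask: np.ndarray | None = None,
                      ) -> tuple[np.ndarray, np.ndarray, float]:
    """Discrepancies D = (O - E)^2 / E and their sum T, with sign(O - E)."""
    O = np.asarray(O, dtype=float)
    E = np.asarray(E, dtype=float)
    if O.shape != E.shape:
        raise ArmdynError(f"shape mismatch: O {O.shape} vs E {E.shape}")
    if mask is None:
        mask = np.ones(O.shape, dtype=bool)
    D = np.zeros_like(E)
    D[mask] = (O[mask] - E[mask]) ** 2 / E[mask]
    sign = np.sign(O - E)
    return D, sign, float(D.sum())


def asymptotic_pvalue(statistic: float, df: int) -> float:
    """Upper-tail chi-squared probability (valid for large N)."""
    if statistic < 0:
        raise ArmdynError("statistic must be >= 0")
    if df < 1:
        raise ArmdynError("df must be >= 1")
    return float(stats.chi2.sf(statistic, df))


def _null_statistics(regions1: ArmRegionSet, regions2: ArmRegionSet,
                     E: np.ndarray, mask: np.ndarray, n_homologs: int,
                     n_draws: int, rng: np.random.Generator,
                     batch: int = 200) -> np.ndarray:
    """T for n_draws uniform repositionings of all homolog pairs (vectorized)."""
    inv1 = regions1.regions(include_outside=False)
    inv2 = regions2.regions(include_outside=False)
    s1 = np.array([r.start for r in inv1]); e1 = np.array([r.end for r in inv1])
    s2 = np.array([r.start for r in inv2]); e2 = np.array([r.end for r in inv2])
    out = np.empty(n_draws)
    done = 0
    while done < n_draws:
        b = min(batch, n_draws - done)
        p1 = rng.uniform(0, regions1.arm_length, size=(b, n_homologs))
        p2 = rng.uniform(0, regions2.arm_length, size=(b, n_homologs))
        m1 = (p1[..., None] >= s1) & (p1[..., None] < e1)   # (b, N, n1)
        m2 = (p2[..., None] >= s2) & (p2[..., None] < e2)
        O = np.einsum("bni,bnj->bij", m1.astype(np.float64), m2.astype(np.float64))
        D = np.where(mask, (O - E) ** 2 / np.where(mask, E, 1.0), 0.0)
        out[done:done + b] = D.sum(axis=(1, 2))
        done += b
    return out


def monte_carlo_pvalue(map1: MarkerMap, map2: MarkerMap,
                       regions1: ArmRegionSet, regions2: ArmRegionSet,
                       homologs: HomologTable | None = None,
                       n_draws: int = 10_000, seed: int = 0,
                       keep_null_sample: bool = False) -> SharingTestResult:
    """Full sharing test: observed statistic, asymptotic and simulated p-values.

    Each draw repositions every homolog pair uniformly and independently on
    its two arms, recounts the matrix and recomputes the statistic against the
    ORIGINAL expected counts. The simulated p-value is the plain proportion of
    draws with a statistic >= the observed one (ties count as exceedances);
    zero exceedances are reported as ``< 1/n_draws`` by the formatter.
    """
    if n_draws < 1:
        raise ArmdynError("n_draws must be >= 1")
    table = count_shared(map1, map2, regions1, regions2, homologs)
    O, E, mask, _ = expected_counts(table, scope="inversions")
    D, sign, T = sharing_statistic(O, E, mask)
    df = int(mask.sum())
    rng = np.random.default_rng(seed)
    null = _null_statistics(regions1, regions2, E, mask, table.n_homologs, n_draws, rng)
    n_exceed = int((null >= T).sum())
    return SharingTestResult(
        region_ids1=[table.region_ids1[i] for i in table.inversion_index1],
        region_ids2=[table.region_ids2[j] for j in table.inversion_index2],
        O=O, E=E, D=D, sign=sign, statistic=T, df=df,
        p_asymptotic=asymptotic_pvalue(T, df),
        p_simulated=n_exceed / n_draws, n_draws=n_draws, n_exceed=n_exceed,
        seed=seed, null_sample=null if keep_null_sample else None,
    )
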