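"""Multi-distance ensembling via a multistage min-P permutation procedure.

The omnibus statistic is the smallest single-distance p-value.  One shared
set of permutation (or bootstrap) draws indexes all K distances within a
replicate, which preserves the correlation structure among the per-distance
statistics.  The procedure:

1. observed pseudo-F per distance;
2. B shared null draws -> F_k(b);
3. per-distance p_k from the draws; if p_min < 1/(tol*B) double B and redo;
4. permuted 'p-values' p_k(b) = (B - rank(F_k(b)))/B, ascending rank with
   ties taking the maximum rank of the tied block, i.e. the strict-exceedance
   proportion #{b': F_k(b') > F_k(b)} / B;
5. p_min(b) = min_k p_k(b);
6. omnibus p = proportion of p_min(b) strictly below p_min (an add-one
   variant is reported alongside so the result is never exactly zero).

A Bonferroni comparator (K * p_min capped at 1) and a maxF comparator (the
maximum pseudo-F across distances, permutation-calibrated) are provided for
reference; the min-P statistic itself is scale-free across distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core_io import ValidationError
from .distances import DistanceSpec
from .permanova import TestSpec, _f_stats, gower_center, null_design


@dataclass
class UnifiedConfig:
    """Distance ensemble plus the permutation-escalation schedule."""

    distances: Optional[Sequence[DistanceSpec]] = None
    b_initial: int = 500
    tol: float = 0.1
    b_max: int = 1_000_000
    seed: int = 0

    def __post_init__(self):
        if self.b_initial < 100:
            raise ValidationError("b_initial must be >= 100")
        if not 0.0 < self.tol < 1.0:
            raise ValidationError("tol must lie strictly between 0 and 1")
        if self.b_max < self.b_initial:
            raise ValidationError("b_max must be >= b_initial")


@dataclass
class UnifiedResult:
    distance_labels: list
    f_observed: np.ndarray
    p_values: np.ndarray
    p_min: float
    p_unified: float
    p_unified_add_one: float
    p_bonferroni: float
    b_final: int
    at_cap: bool = False
    p_max_f: Optional[float] = None

    def __post_init__(self):
        # the omnibus p-value can never undercut the minimum single-distance p
        if self.p_unified < self.p_min - 1e-12:
            raise AssertionError("unified p fell below p_min; internal bookkeeping error")


def escalate_b(current_b: int, p_min: float, tol: float) -> Optional[int]:
    """Double the permutation count while the achieved resolution is too
    coarse (p_min < 1/(tol*B)); return None once it suffices."""
    if p_min < 1.0 / (tol * current_b):
        return 2 * current_b
    return None


def bonferroni_min_p(p_values) -> float:
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        raise ValidationError("empty p-value list")
    if ((p_values < 0) | (p_values > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return float(min(1.0, p_values.size * p_values.min()))


def _strict_exceedance_p(f_row: np.ndarray) -> np.ndarray:
    """p_k(b) = #{b': F(b') > F(b)} / B via sorting."""
    b = len(f_row)
    srt = np.sort(f_row)
    return (b - np.searchsorted(srt, f_row, side="right")) / b


def _unified_from_f(f_obs: np.ndarray, f_perm: np.ndarray):
    """Steps 3-6 given observed (K,) and permuted (K, B) pseudo-F arrays."""
    k, b = f_perm.shape
    count_ge = (f_perm >= f_obs[:, None]).sum(axis=1)
    p_k = (1 + count_ge) / (b + 1)
    p_min = float(p_k.min())
    p_kb = np.empty_like(f_perm)
    for i in range(k):
        p_kb[i] = _strict_exceedance_p(f_perm[i])
    p_min_b = p_kb.min(axis=0)
    count = int((p_min_b < p_min).sum())
    return p_k, p_min, count / b, (1 + count) / (b + 1)


def unified_test(d_list: Sequence, spec: TestSpec, config: UnifiedConfig, include_max_f: bool = False) -> UnifiedResult:
    """Run the min-P omnibus test over several distance matrices sharing one
    stream of null draws.

    ``d_list`` may hold :class:`~microbeta.core_io.DistanceMatrix` objects or
    plain square arrays; all must share sample order.  The labels come from
    ``config.distances`` when given, else are positional.
    """
    if len(d_list) == 0:
        raise ValidationError("at least one distance matrix is required")
    shapes = set()
    for d in d_list:
        ids = getattr(d, "sample_ids", None)
        shapes.add(tuple(ids) if ids is not None else np.asarray(d).shape)
    if len(shapes) > 1:
        raise ValidationError("all distance matrices must share sample ids and ordering")
    g_list = [gower_center(d) for d in d_list]
    labels = (
        [s.label for s in config.distances]
        if config.distances is not None and len(config.distances) == len(d_list)
        else [f"distance_{i}" for i in range(len(d_list))]
    )

    rng = np.random.default_rng(config.seed)
    b = config.b_initial
    at_cap = False
    while True:
        r_obs, r_mat = null_design(spec, b, rng)
        f_obs = np.empty(len(g_list))
        f_perm = np.empty((len(g_list), b))
        for i, g in enumerate(g_list):
            f_obs[i], f_perm[i] = _f_stats(g, r_obs, r_mat)
        count_ge = (f_perm >= f_obs[:, None]).sum(axis=1)
        p_min_now = float(((1 + count_ge) / (b + 1)).min())
        new_b = escalate_b(b, p_min_now, config.tol)
        if new_b is None:
            break
        if b >= config.b_max:
            at_cap = True
            break
        b = min(new_b, config.b_max)

    p_k, p_min, p_uni, p_uni_add1 = _unified_from_f(f_obs, f_perm)
    result = UnifiedResult(
        distance_labels=labels,
        f_observed=f_obs,
        p_values=p_k,
        p_min=p_min,
        p_unified=p_uni,
        p_unified_add_one=p_uni_add1,
        p_bonferroni=bonferroni_min_p(p_k),
        b_final=b,
        at_cap=at_cap,
    )
    if include_max_f:
        max_obs = f_obs.max()
        max_perm = f_perm.max(axis=0)
        result.p_max_f = float((1 + (max_perm >= max_obs).sum()) / (b + 1))
    return result


def max_f_test(d_list: Sequence, spec: TestSpec, b: int, seed: int = 0) -> float:
    """Comparator: permutation p-value of the maximum pseudo-F across
    distances (scale-sensitive, unlike the min-P statistic)."""
    if len(d_list) == 0:
        raise ValidationError("at least one distance matrix is required")
    g_list = [gower_center(d) for d in d_list]
    rng = np.random.default_rng(seed)
    r_obs, r_mat = null_design(spec, b, rng)
    f_obs = np.empty(len(g_list))
    f_perm = np.empty((len(g_list), b))
    for i, g in enumerate(g_list):
        f_obs[i], f_perm[i] = _f_stats(g, r_obs, r_mat)
    max_obs = f_obs.max()
    max_perm = f_perm.max(axis=0)
    return float((1 + (max_perm >= max_obs).sum()) / (b + 1))
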