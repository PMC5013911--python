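"""Beta-diversity distances.

Six distances are provided: two abundance distances that ignore the tree
(Bray-Curtis) or use it (weighted / generalized UniFrac), and three
presence-absence distances (Jaccard, unweighted UniFrac, presence-weighted
UniFrac).  Presence-weighted UniFrac weights each branch by the relative
richness difference ``|n_jl - n_kl| / (n_jl + n_kl)`` where ``n_jl`` counts
the present OTUs descending from branch ``l`` in sample ``j``; the exponent
``alpha`` in ``(n_jl + n_kl)^alpha`` attenuates the contribution of
high-richness branches, exactly mirroring how generalized UniFrac attenuates
high-abundance branches.

Branches with zero combined mass for a pair are excluded from both numerator
and denominator of the alpha-weighted variants (``0^0`` would otherwise
inject spurious weight), which preserves ``D(x, x) = 0`` and the exact
reduction of the generalized form to weighted UniFrac at ``alpha = 1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core_io import (
    DistanceMatrix,
    OtuTable,
    PhyloTree,
    PresenceTable,
    ProportionTable,
    ValidationError,
    to_presence,
    to_proportions,
)

VALID_NAMES = ("bray_curtis", "jaccard", "w_unifrac", "gw_unifrac", "uw_unifrac", "pw_unifrac")
TREE_BASED = frozenset({"w_unifrac", "gw_unifrac", "uw_unifrac", "pw_unifrac"})
ALPHA_BASED = frozenset({"gw_unifrac", "pw_unifrac"})
PRESENCE_BASED = frozenset({"jaccard", "uw_unifrac", "pw_unifrac"})


@dataclass(frozen=True)
class DistanceSpec:
    """Name of a distance plus, for the alpha-weighted UniFrac variants,
    the attenuation exponent in [0, 1]."""

    name: str
    alpha: Optional[float] = None

    def __post_init__(self):
        if self.name not in VALID_NAMES:
            raise ValidationError(f"unknown distance {self.name!r}; choose from {VALID_NAMES}")
        if self.name in ALPHA_BASED:
            if self.alpha is None:
                raise ValidationError(f"{self.name} requires an alpha in [0, 1]")
            if not 0.0 <= self.alpha <= 1.0:
                raise ValidationError(f"alpha must be in [0, 1], got {self.alpha}")
        elif self.alpha is not None:
            raise ValidationError(f"{self.name} does not take an alpha parameter")

    @property
    def label(self) -> str:
        if self.alpha is None:
            return self.name
        return f"{self.name}_{self.alpha:g}"

    @property
    def needs_tree(self) -> bool:
        return self.name in TREE_BASED

    @classmethod
    def parse(cls, text: str) -> "DistanceSpec":
        """Parse 'name' or 'name:alpha' (e.g. ``pw_unifrac:0.5``)."""
        if ":" in text:
            name, alpha = text.split(":", 1)
            return cls(name.strip(), float(alpha))
        return cls(text.strip())


DEFAULT_SPECS = (
    DistanceSpec("w_unifrac"),
    DistanceSpec("bray_curtis"),
    DistanceSpec("pw_unifrac", 1.0),
    DistanceSpec("pw_unifrac", 0.0),
    DistanceSpec("uw_unifrac"),
    DistanceSpec("jaccard"),
)


@dataclass
class BranchProfile:
    """Per-branch views of a set of samples on a tree.

    ``abundance[j, l]`` is the proportion of sample ``j``'s community
    descending from branch ``l``; ``richness[j, l]`` is the number of its
    present OTUs descending from branch ``l``.  Branch order follows a
    post-order traversal with the root excluded.
    """

    sample_ids: list
    branch_lengths: np.ndarray  # (L,)
    abundance: np.ndarray  # (n, L)
    richness: np.ndarray  # (n, L)


def leaf_descendant_matrix(tree: PhyloTree, otu_ids: Sequence[str]):
    """Indicator matrix A (m x L): A[i, l] = 1 iff table OTU i is a leaf
    below branch l.  Also returns the branch-length vector (L,).

    Tree leaves without a matching table OTU are retained (their branches
    still count toward total branch length) but contribute no mass.
    """
    col = {o: i for i, o in enumerate(otu_ids)}
    missing = [o for o in otu_ids if o not in set(tree.leaf_names)]
    if missing:
        raise ValidationError(f"OTU id(s) not found as tree leaves: {missing[:10]}")
    if len(tree.leaf_names) < 2:
        raise ValidationError("tree must have at least 2 leaves")
    branches = []
    lengths = []
    leafsets: dict = {}
    for node in tree.tree.postorder(include_self=False):
        if node.is_tip():
            leafsets[id(node)] = [col[node.name]] if node.name in col else []
        else:
            acc: list = []
            for child in node.children:
                acc.extend(leafsets[id(child)])
            leafsets[id(node)] = acc
        branches.append(node)
        lengths.append(node.length)
    L = len(branches)
    A = np.zeros((len(otu_ids), L))
    for l, node in enumerate(branches):
        A[leafsets[id(node)], l] = 1.0
    return A, np.asarray(lengths, dtype=float)


def branch_profiles(tree: PhyloTree, props: ProportionTable, presence: PresenceTable) -> BranchProfile:
    """Accumulate leaf proportions and presence indicators up the tree."""
    if list(props.otu_ids) != list(presence.otu_ids) or list(props.sample_ids) != list(presence.sample_ids):
        raise ValidationError("proportion and presence tables must share axes")
    A, lengths = leaf_descendant_matrix(tree, props.otu_ids)
    abundance = props.values @ A
    richness = presence.values.astype(float) @ A
    return BranchProfile(list(props.sample_ids), lengths, abundance, richness)


# ---------------------------------------------------------------------------
# pairwise operations

def bray_curtis(p_j, p_k) -> float:
    p_j = np.asarray(p_j, dtype=float)
    p_k = np.asarray(p_k, dtype=float)
    if p_j.shape != p_k.shape:
        raise ValidationError("vectors must have equal length")
    if (p_j < 0).any() or (p_k < 0).any():
        raise ValidationError("abundances must be non-negative")
    total = p_j.sum() + p_k.sum()
    if total == 0:
        raise ValidationError("Bray-Curtis undefined: both samples are all-zero")
    return float(np.abs(p_j - p_k).sum() / total)


def jaccard(a_j, a_k) -> float:
    a_j = np.asarray(a_j)
    a_k = np.asarray(a_k)
    if a_j.shape != a_k.shape:
        raise ValidationError("vectors must have equal length")
    if not (np.isin(a_j, (0, 1)).all() and np.isin(a_k, (0, 1)).all()):
        raise ValidationError("Jaccard requires binary presence vectors")
    n11 = int(((a_j == 1) & (a_k == 1)).sum())
    n01 = int((a_j != a_k).sum())
    if n01 + n11 == 0:
        raise ValidationError("Jaccard undefined: no species present in either sample")
    return n01 / (n01 + n11)


def _sample_index(profile: BranchProfile, j) -> int:
    if isinstance(j, str):
        return profile.sample_ids.index(j)
    return int(j)


def weighted_unifrac(profile: BranchProfile, j, k) -> float:
    j, k = _sample_index(profile, j), _sample_index(profile, k)
    b = profile.branch_lengths
    pj, pk = profile.abundance[j], profile.abundance[k]
    den = float((b * (pj + pk)).sum())
    if den == 0:
        raise ValidationError("weighted UniFrac undefined: zero total branch mass")
    return float((b * np.abs(pj - pk)).sum() / den)


def _alpha_weighted(b, u, v, alpha: float) -> float:
    tot = u + v
    occ = tot > 0
    if not occ.any():
        raise ValidationError("no occupied branch for this sample pair")
    w = b[occ] * tot[occ] ** alpha
    den = float(w.sum())
    if den == 0:
        raise ValidationError("zero denominator in alpha-weighted UniFrac")
    ratio = np.abs(u[occ] - v[occ]) / tot[occ]
    return float((w * ratio).sum() / den)


def generalized_unifrac(profile: BranchProfile, j, k, alpha: float) -> float:
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError(f"alpha must be in [0, 1], got {alpha}")
    j, k = _sample_index(profile, j), _sample_index(profile, k)
    return _alpha_weighted(profile.branch_lengths, profile.abundance[j], profile.abundance[k], alpha)


def unweighted_unifrac(profile: BranchProfile, j, k) -> float:
    j, k = _sample_index(profile, j), _sample_index(profile, k)
    b = profile.branch_lengths
    total = float(b.sum())
    if total == 0:
        raise ValidationError("unweighted UniFrac undefined: zero total branch length")
    ij = (profile.richness[j] > 0).astype(float)
    ik = (profile.richness[k] > 0).astype(float)
    return float((b * np.abs(ij - ik)).sum() / total)


def presence_weighted_unifrac(profile: BranchProfile, j, k, alpha: float) -> float:
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError(f"alpha must be in [0, 1], got {alpha}")
    j, k = _sample_index(profile, j), _sample_index(profile, k)
    return _alpha_weighted(profile.branch_lengths, profile.richness[j], profile.richness[k], alpha)


# ---------------------------------------------------------------------------
# vectorised matrix computation

def _pair_indices(n: int):
    return np.triu_indices(n, k=1)


def _condensed_alpha(b, M, alpha: float) -> np.ndarray:
    """Alpha-weighted UniFrac over all pairs of rows of M (abundance or
    richness at branch level).

    alpha = 1 collapses to a weighted city-block distance; the general case
    runs in pair chunks with in-place arithmetic to keep allocation flat.
    """
    n = M.shape[0]
    iu, ju = _pair_indices(n)
    if alpha == 1.0:
        num = pdist(M * b[None, :], "cityblock")
        s = M @ b
        den = s[iu] + s[ju]
        if (den == 0).any():
            raise ValidationError("sample pair with no occupied branch")
        return num / den
    n_pairs = len(iu)
    num = np.empty(n_pairs)
    den = np.empty(n_pairs)
    chunk = max(1, int(4_000_000 // max(M.shape[1], 1)))
    for lo in range(0, n_pairs, chunk):
        sl = slice(lo, lo + chunk)
        u = M[iu[sl]]
        v = M[ju[sl]]
        tot = u + v
        diff = np.abs(u - v)
        occ = tot > 0
        np.divide(diff, tot, out=diff, where=occ)  # relative difference
        if alpha == 0.0:
            w = occ * b[None, :]
        else:
            w = np.where(occ, tot, 1.0) ** alpha
            w *= b[None, :]
            w *= occ
        diff *= w
        num[sl] = diff.sum(axis=1)
        den[sl] = w.sum(axis=1)
    if (den == 0).any():
        raise ValidationError("sample pair with no occupied branch")
    return num / den


def condensed_distances(
    spec: DistanceSpec,
    props: np.ndarray,
    presence: np.ndarray,
    branch_abundance: Optional[np.ndarray] = None,
    branch_richness: Optional[np.ndarray] = None,
    branch_lengths: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Condensed (upper-triangle) distance vector for one spec.

    ``props``/``presence`` are sample x OTU arrays; the branch-level arrays
    are required for tree-based specs.  This is the fast path shared by
    :func:`distance_matrix` and the simulation experiments.
    """
    n = props.shape[0]
    iu, ju = _pair_indices(n)
    if spec.name == "bray_curtis":
        num = pdist(props, "cityblock")
        t = props.sum(axis=1)
        den = t[iu] + t[ju]
        if (den == 0).any():
            raise ValidationError("Bray-Curtis undefined for a pair of all-zero samples")
        return num / den
    if spec.name == "jaccard":
        pres = presence.astype(float)
        n11 = (pres @ pres.T)[iu, ju]
        r = pres.sum(axis=1)
        n01 = r[iu] + r[ju] - 2 * n11
        den = n01 + n11
        if (den == 0).any():
            raise ValidationError("Jaccard undefined for a pair of all-empty samples")
        return n01 / den
    b = branch_lengths
    if b is None:
        raise ValidationError(f"{spec.name} requires a phylogenetic tree")
    if spec.name == "w_unifrac":
        num = pdist(branch_abundance * b[None, :], "cityblock")
        s = branch_abundance @ b
        den = s[iu] + s[ju]
        if (den == 0).any():
            raise ValidationError("weighted UniFrac undefined: pair with zero branch mass")
        return num / den
    if spec.name == "gw_unifrac":
        return _condensed_alpha(b, branch_abundance, spec.alpha)
    if spec.name == "pw_unifrac":
        return _condensed_alpha(b, branch_richness, spec.alpha)
    if spec.name == "uw_unifrac":
        total = b.sum()
        if total == 0:
            raise ValidationError("unweighted UniFrac undefined: zero total branch length")
        ind = (branch_richness > 0).astype(float) * b[None, :]
        return pdist(ind, "cityblock") / total
    raise AssertionError(spec.name)


def distance_matrix(table: OtuTable, spec: DistanceSpec, tree: Optional[PhyloTree] = None) -> DistanceMatrix:
    """Apply the pairwise distance to every pair of samples.

    Zero-total samples are dropped with a warning rather than producing NaN
    rows.  A tree is required exactly for the UniFrac variants.
    """
    if spec.needs_tree and tree is None:
        raise ValidationError(f"{spec.name} requires a phylogenetic tree")
    return distance_matrices(table, [spec], tree)[0]


def distance_matrices(
    table: OtuTable, specs: Sequence[DistanceSpec], tree: Optional[PhyloTree] = None
) -> list:
    """Compute several distance matrices, sharing the branch profile work."""
    totals = table.sample_totals
    if (totals == 0).any():
        dropped = [table.sample_ids[i] for i in np.flatnonzero(totals == 0)]
        warnings.warn(
            f"excluding {len(dropped)} zero-total sample(s) from distance computation: {dropped}",
            UserWarning,
            stacklevel=2,
        )
        keep = np.flatnonzero(totals > 0)
        table = OtuTable([table.sample_ids[i] for i in keep], list(table.otu_ids), table.counts[keep])
    if table.n_samples < 2:
        raise ValidationError("need at least 2 samples with positive totals")
    props = to_proportions(table)
    presence = to_presence(table)
    needs_tree = any(s.needs_tree for s in specs)
    if needs_tree:
        if tree is None:
            raise ValidationError("a phylogenetic tree is required for UniFrac distances")
        profile = branch_profiles(tree, props, presence)
        ba, br, b = profile.abundance, profile.richness, profile.branch_lengths
    else:
        ba = br = b = None
    out = []
    for spec in specs:
        cond = condensed_distances(spec, props.values, presence.values, ba, br, b)
        out.append(DistanceMatrix(list(table.sample_ids), squareform(cond)))
    return out
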