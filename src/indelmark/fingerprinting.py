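"""Codominant allele calling, band scoring, diversity analysis and
minimum discriminating marker sets.

A codominant InDel marker amplifies a reference-size fragment (allele A) and
an alternative-size fragment (allele B); a heterozygote shows both (H). A
single fragment at least ``novel_allele_threshold`` bp larger than both
expected sizes is a novel allele, lettered C, D, ... in order of first
detection across accessions. Band presence/absence per fragment class is
scored 1/0, pairwise similarity is Jaccard's coefficient over bands (joint
absences excluded), and accessions are clustered by UPGMA on 1 - similarity.
The minimum discriminating set is the smallest marker subset under which all
accessions have distinct allele profiles.
"""

from __future__ import annotations

import itertools
import logging
import string
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .config import RunConfig
from .io_core import round_half_up

logger = logging.getLogger(__name__)

# novel fragment classes letter from C in detection order; A/B are the
# expected alleles and H the heterozygote, so those letters are skipped
_NOVEL_LETTERS = "".join(c for c in string.ascii_uppercase if c not in "ABH")


@dataclass(frozen=True)
class AlleleCall:
    """One accession's scored genotype at one marker.

    ``call`` is 'A', 'B', 'H', a novel-allele letter ('C', 'D', ...), or
    None when no product amplified. Unscoreable fragment patterns are
    flagged ``ambiguous`` rather than silently assigned.
    """

    marker_id: str
    accession_id: str
    call: str | None
    fragments: tuple[int, ...] = ()
    ambiguous: bool = False


def _matches(size: int, expected: int, tol: int) -> bool:
    return abs(size - expected) <= tol


def call_alleles(
    observed: Mapping[str, Sequence[int]],
    expected_ref: int,
    expected_alt: int,
    cfg: RunConfig | None = None,
    marker_id: str = "marker",
) -> dict[str, AlleleCall]:
    """Score one marker's fragment sizes into codominant allele calls.

    ``observed`` maps accession id to that accession's fragment sizes (bp),
    in scoring order (M01 first): novel-allele letters are assigned to
    distinct oversized fragments in the order they are first seen. A
    fragment within ``cfg.fragment_tolerance`` bp of an expected size counts
    as that allele; a single fragment at least ``cfg.novel_allele_threshold``
    bp larger than both expected sizes starts (or joins) a novel class;
    anything else is flagged ambiguous.
    """
    cfg = cfg or RunConfig()
    if abs(expected_ref - expected_alt) < cfg.min_size_diff:
        raise ValueError(
            f"{marker_id}: expected sizes {expected_ref}/{expected_alt} differ "
            f"by less than min_size_diff ({cfg.min_size_diff} bp)"
        )
    tol = cfg.fragment_tolerance
    novel_classes: list[int] = []  # representative size per novel letter
    calls: dict[str, AlleleCall] = {}
    for accession, sizes in observed.items():
        sizes = tuple(int(s) for s in sizes)
        if any(s <= 0 for s in sizes):
            raise ValueError(f"{marker_id}/{accession}: non-positive fragment size")
        result: str | None = None
        ambiguous = False
        if len(sizes) == 0:
            result = None
        elif len(sizes) == 1:
            (size,) = sizes
            is_ref = _matches(size, expected_ref, tol)
            is_alt = _matches(size, expected_alt, tol)
            if is_ref and is_alt:
                ambiguous = True
            elif is_ref:
                result = "A"
            elif is_alt:
                result = "B"
            elif (
                size >= expected_ref + cfg.novel_allele_threshold
                and size >= expected_alt + cfg.novel_allele_threshold
            ):
                for idx, known in enumerate(novel_classes):
                    if _matches(size, known, tol):
                        result = _NOVEL_LETTERS[idx]
                        break
                else:
                    novel_classes.append(size)
                    result = _NOVEL_LETTERS[len(novel_classes) - 1]
            else:
                ambiguous = True
        elif len(sizes) == 2:
            lo, hi = sorted(sizes)
            exp_lo, exp_hi = sorted((expected_ref, expected_alt))
            if _matches(lo, exp_lo, tol) and _matches(hi, exp_hi, tol):
                result = "H"
            else:
                ambiguous = True
        else:
            ambiguous = True
        calls[accession] = AlleleCall(
            marker_id=marker_id,
            accession_id=accession,
            call=None if ambiguous else result,
            fragments=sizes,
            ambiguous=ambiguous,
        )
    n_amb = sum(c.ambiguous for c in calls.values())
    if n_amb:
        logger.warning("%s: %d ambiguous fragment pattern(s)", marker_id, n_amb)
    return calls


def score_bands(
    allele_matrix: pd.DataFrame, single_band_per_marker: bool = False
) -> pd.DataFrame:
    """Expand an accessions x markers call matrix into a binary band matrix.

    Default (codominant) encoding gives every marker an A-fragment and a
    B-fragment column plus one column per novel allele letter observed; an H
    call lights both parental columns, a null call none. With
    ``single_band_per_marker`` the alternative dominant reading is produced:
    one column per marker, 1 for any amplified product.
    """
    accessions = list(allele_matrix.index)
    data: dict[str, list[int]] = {}
    for marker in allele_matrix.columns:
        calls = allele_matrix[marker]
        if single_band_per_marker:
            data[str(marker)] = [0 if calls[a] is None else 1 for a in accessions]
            continue
        letters = ["A", "B"] + sorted(
            {c for c in calls if isinstance(c, str) and c in _NOVEL_LETTERS}
        )
        for letter in letters:
            col = []
            for a in accessions:
                call = calls[a]
                if call == "H":
                    col.append(int(letter in ("A", "B")))
                else:
                    col.append(int(call == letter))
            data[f"{marker}:{letter}"] = col
    return pd.DataFrame(data, index=accessions, dtype=int)


def jaccard_matrix(
    band_matrix: pd.DataFrame, count_joint_absences: bool = False
) -> pd.DataFrame:
    """Pairwise Jaccard similarity over band columns.

    S(i,j) = n11 / (n11 + n10 + n01); bands absent in both accessions do not
    enter the denominator (set ``count_joint_absences`` for the simple
    matching coefficient instead). Raises if a pair shares no scored band.
    """
    X = band_matrix.to_numpy(dtype=bool)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two accessions")
    labels = list(band_matrix.index)
    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            n11 = int(np.sum(X[i] & X[j]))
            n_mismatch = int(np.sum(X[i] ^ X[j]))
            n00 = int(np.sum(~X[i] & ~X[j]))
            if count_joint_absences:
                S[i, j] = S[j, i] = (n11 + n00) / X.shape[1]
            else:
                union = n11 + n_mismatch
                if union == 0:
                    raise ValueError(
                        f"accessions {labels[i]} and {labels[j]} share no "
                        "scored band; Jaccard similarity undefined"
                    )
                S[i, j] = S[j, i] = n11 / union
    return pd.DataFrame(S, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# UPGMA

@dataclass(frozen=True)
class _Node:
    height: float
    name: str | None = None
    children: tuple["_Node", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass(frozen=True)
class UPGMATree:
    """Ultrametric agglomerative tree: every leaf is equidistant from root."""

    root: _Node

    @property
    def leaves(self) -> list[str]:
        out: list[str] = []

        def walk(node: _Node) -> None:
            if node.is_leaf:
                out.append(node.name or "")
            for child in node.children:
                walk(child)

        walk(self.root)
        return out

    def leaf_depths(self) -> dict[str, float]:
        depths: dict[str, float] = {}

        def walk(node: _Node, above: float) -> None:
            if node.is_leaf:
                depths[node.name or ""] = above + node.height
            for child in node.children:
                walk(child, above + (node.height - child.height))

        walk(self.root, 0.0)
        return depths

    def to_treenode(self) -> TreeNode:
        def convert(node: _Node, parent_height: float | None) -> TreeNode:
            length = None if parent_height is None else parent_height - node.height
            tn = TreeNode(name=node.name, length=length)
            tn.extend([convert(c, node.height) for c in node.children])
            return tn

        return convert(self.root, None)

    def newick(self) -> str:
        return str(self.to_treenode())


def upgma(distance: pd.DataFrame) -> UPGMATree:
    """Average-linkage (UPGMA) agglomeration of a distance matrix.

    The matrix must be symmetric with a zero diagonal. Clusters join at
    height = distance / 2; inter-cluster distances are size-weighted
    arithmetic means of leaf-pair distances. When several pairs tie for the
    minimum, the pair whose (smallest-leaf-label, smallest-leaf-label) key
    sorts first is joined, making the tree deterministic.
    """
    D = distance.to_numpy(dtype=float)
    labels = [str(x) for x in distance.index]
    n = len(labels)
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    if np.any(np.diag(D) != 0) or np.any(D < 0):
        raise ValueError("distance matrix needs a zero diagonal and no negatives")
    if n == 1:
        return UPGMATree(root=_Node(height=0.0, name=labels[0]))

    clusters: dict[int, dict] = {
        i: {"node": _Node(height=0.0, name=labels[i]), "size": 1, "key": labels[i]}
        for i in range(n)
    }
    dist: dict[frozenset[int], float] = {
        frozenset((i, j)): D[i, j] for i in range(n) for j in range(i + 1, n)
    }
    next_id = n
    while len(clusters) > 1:
        def order(pair: frozenset[int]) -> tuple:
            i, j = sorted(pair, key=lambda c: clusters[c]["key"])
            return (dist[pair], clusters[i]["key"], clusters[j]["key"])

        best = min(dist, key=order)
        i, j = sorted(best, key=lambda c: clusters[c]["key"])
        d_ij = dist[best]
        height = d_ij / 2.0
        merged = {
            "node": _Node(
                height=height,
                children=(clusters[i]["node"], clusters[j]["node"]),
            ),
            "size": clusters[i]["size"] + clusters[j]["size"],
            "key": min(clusters[i]["key"], clusters[j]["key"]),
        }
        ni, nj = clusters[i]["size"], clusters[j]["size"]
        for k in list(clusters):
            if k in (i, j):
                continue
            d_new = (
                ni * dist[frozenset((k, i))] + nj * dist[frozenset((k, j))]
            ) / (ni + nj)
            dist[frozenset((k, next_id))] = d_new
        for pair in [p for p in dist if p & {i, j}]:
            del dist[pair]
        del clusters[i], clusters[j]
        clusters[next_id] = merged
        next_id += 1
    (root,) = clusters.values()
    return UPGMATree(root=root["node"])


# ---------------------------------------------------------------------------
# Minimum discriminating marker set

@dataclass(frozen=True)
class MinSetResult:
    markers: tuple[str, ...] | None
    optimal: bool
    discriminates: bool


def _profiles_distinct(allele_matrix: pd.DataFrame, markers: Sequence[str]) -> bool:
    profiles = [tuple(allele_matrix.loc[a, m] for m in markers) for a in allele_matrix.index]
    return len(set(profiles)) == len(profiles)


def min_discriminating_set(
    allele_matrix: pd.DataFrame,
    max_k: int | None = None,
    exhaustive_limit: int = 25,
) -> MinSetResult:
    """Smallest marker subset giving every accession a distinct profile.

    Subset sizes are searched exhaustively from 1 upward (lexicographically
    first solution among equal-size ones) while the marker panel has at most
    ``exhaustive_limit`` markers; larger panels fall back to greedy
    partition refinement, and the result is labeled non-optimal.
    """
    markers = sorted(str(m) for m in allele_matrix.columns)
    if max_k is None:
        max_k = len(markers)
    if not _profiles_distinct(allele_matrix, markers):
        return MinSetResult(markers=None, optimal=True, discriminates=False)
    if len(markers) <= exhaustive_limit:
        for k in range(1, max_k + 1):
            for combo in itertools.combinations(markers, k):
                if _profiles_distinct(allele_matrix, combo):
                    return MinSetResult(markers=combo, optimal=True, discriminates=True)
        return MinSetResult(markers=None, optimal=True, discriminates=True)
    # greedy partition refinement (heuristic)
    chosen: list[str] = []
    blocks = [tuple(allele_matrix.index)]
    while any(len(b) > 1 for b in blocks) and len(chosen) < max_k:
        best_marker = None
        best_blocks = blocks
        best_count = len(blocks)
        for m in markers:  # lexicographic order => deterministic tie-break
            if m in chosen:
                continue
            refined = []
            for block in blocks:
                groups: dict[object, list] = {}
                for a in block:
                    groups.setdefault(allele_matrix.loc[a, m], []).append(a)
                refined.extend(tuple(g) for g in groups.values())
            if len(refined) > best_count:
                best_marker, best_blocks, best_count = m, refined, len(refined)
        if best_marker is None:
            break
        chosen.append(best_marker)
        blocks = best_blocks
    if all(len(b) == 1 for b in blocks):
        return MinSetResult(markers=tuple(sorted(chosen)), optimal=False, discriminates=True)
    return MinSetResult(markers=None, optimal=False, discriminates=True)


# ---------------------------------------------------------------------------
# Validation accounting

@dataclass(frozen=True)
class MarkerValidation:
    """Wet-lab outcome for one tested marker."""

    marker_id: str
    amplified: bool
    polymorphic: bool
    calls: Mapping[str, str | None] | None = None

    def __post_init__(self) -> None:
        if not self.amplified and self.polymorphic:
            raise ValueError(
                f"{self.marker_id}: cannot be polymorphic without amplification"
            )


@dataclass
class ValidationSummary:
    total: int
    n_polymorphic: int
    n_failed: int
    n_monomorphic: int
    pct_polymorphic: int
    pct_failed: int
    pct_monomorphic: int
    n_expected_pattern: int
    n_with_het: int
    pairwise_polymorphic: pd.DataFrame | None = None


def validation_summary(
    outcomes: Sequence[MarkerValidation], target_code: str = "303"
) -> ValidationSummary:
    """Tally marker-validation outcomes into counts and whole percentages.

    Categories (polymorphic / failed amplification / amplified but
    monomorphic) are mutually exclusive and sum to the number of tested
    markers. When per-accession calls are supplied, also counts markers
    whose A/B pattern matches the expected target code exactly, markers with
    at least one heterozygous call, and — per accession pair — markers whose
    calls differ between the two accessions.
    """
    total = len(outcomes)
    n_poly = sum(o.amplified and o.polymorphic for o in outcomes)
    n_fail = sum(not o.amplified for o in outcomes)
    n_mono = sum(o.amplified and not o.polymorphic for o in outcomes)
    assert n_poly + n_fail + n_mono == total

    n_pattern = 0
    n_het = 0
    pairwise = None
    with_calls = [o for o in outcomes if o.calls is not None]
    if with_calls:
        accessions = list(with_calls[0].calls)  # type: ignore[arg-type]
        pair_counts = pd.DataFrame(0, index=accessions, columns=accessions)
        want = tuple(int(d) for d in target_code)
        for o in with_calls:
            calls = o.calls or {}
            values = list(calls.values())
            counts = (
                values.count("A"),
                values.count("H"),
                values.count("B"),
            )
            if counts == want and len(values) == sum(want):
                n_pattern += 1
            if counts[1] > 0:
                n_het += 1
            for a, b in itertools.combinations(accessions, 2):
                ca, cb = calls.get(a), calls.get(b)
                if ca is not None and cb is not None and ca != cb:
                    pair_counts.loc[a, b] += 1
                    pair_counts.loc[b, a] += 1
        pairwise = pair_counts

    def pct(x: int) -> int:
        return int(round_half_up(x / total * 100)) if total else 0

    return ValidationSummary(
        total=total,
        n_polymorphic=n_poly,
        n_failed=n_fail,
        n_monomorphic=n_mono,
        pct_polymorphic=pct(n_poly),
        pct_failed=pct(n_fail),
        pct_monomorphic=pct(n_mono),
        n_expected_pattern=n_pattern,
        n_with_het=n_het,
        pairwise_polymorphic=pairwise,
    )
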