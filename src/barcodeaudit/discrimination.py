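"""Per-species diagnosability: monophyly, haplotype sharing, failure classes.

A species is diagnosable by its barcodes when its specimens form a
monophyletic cluster on the neighbour-joining tree and none of its
haplotypes is identical to a congener's.  Species failing that criterion
are assigned one of five mutually exclusive failure conditions:

* ``PARAPHYLETIC``      - one other species nests, itself monophyletic,
  inside this species' cluster;
* ``POLYPHYLETIC``      - two or more other species interleave with it;
* ``IDENTICAL_SHARED``  - it shares an identical haplotype with a congener;
* ``OVERLAPPING``       - it and a single other species mutually interleave
  without sharing identical haplotypes;
* ``IDENTICAL_AND_OVERLAPPING`` - shares a haplotype and additionally
  interleaves beyond the shared haplotype itself.

Successful species are ``DISTINCT`` (multi-specimen) or
``SINGLETON_DISTINCT`` (one specimen, which cannot demonstrate monophyly
but is counted a success when unshared; reports mark it as untested by
replication).

Monophyly is evaluated on the unrooted topology: a leaf subset is
monophyletic iff some single edge bipartitions the leaves into exactly that
subset and its complement (singletons are trivially monophyletic via their
own pendant edge).  The paraphyly/polyphyly distinction needs a rooted
view; the tree is rooted on a designated outgroup when available, else at
the midpoint, and the choice is logged because pathological root placements
can alter those two labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .distance import encode_sequences, pairwise_counts
from .errors import ValidationError
from .records import Dataset
from .tree import midpoint_root, root_tree

logger = logging.getLogger(__name__)


class Condition(str, Enum):
    DISTINCT = "distinct"
    SINGLETON_DISTINCT = "singleton_distinct"
    PARAPHYLETIC = "paraphyletic"
    POLYPHYLETIC = "polyphyletic"
    IDENTICAL_SHARED = "identical_shared"
    OVERLAPPING = "overlapping"
    IDENTICAL_AND_OVERLAPPING = "identical_and_overlapping"


SUCCESS_CONDITIONS = frozenset({Condition.DISTINCT, Condition.SINGLETON_DISTINCT})


@dataclass(frozen=True)
class SpeciesAssessment:
    """Diagnosability verdict for one species."""

    species: str                       # binomial
    n_specimens: int
    condition: Condition
    congeners_involved: tuple[str, ...] = ()
    shares_haplotype_with: tuple[str, ...] = ()

    @property
    def success(self) -> bool:
        return self.condition in SUCCESS_CONDITIONS


@dataclass(frozen=True)
class HaplotypePair:
    """A cross-species pair of specimens with identical barcodes."""

    specimen_a: str
    specimen_b: str
    species_a: str
    species_b: str


class _TreeIndex:
    """Bitmask leaf sets for every edge of an (unrooted) tree.

    A subset S of leaves is separable by one edge iff S's mask, or its
    complement, equals some node's below-mask.
    """

    def __init__(self, tree: dendropy.Tree):
        self.bit: dict[str, int] = {}
        masks: dict[int, int] = {}
        self.mask_set: set[int] = set()
        for nd in tree.postorder_node_iter():
            if nd.is_leaf():
                b = 1 << len(self.bit)
                self.bit[nd.taxon.label] = b
                masks[id(nd)] = b
            else:
                m = 0
                for c in nd.child_nodes():
                    m |= masks[id(c)]
                masks[id(nd)] = m
            self.mask_set.add(masks[id(nd)])
        self.full = masks[id(tree.seed_node)]

    def mask(self, leaf_ids: Iterable[str]) -> int:
        m = 0
        for s in leaf_ids:
            try:
                m |= self.bit[s]
            except KeyError:
                raise ValidationError(f"unknown leaf: {s}") from None
        return m

    def is_monophyletic(self, leaf_ids: Iterable[str]) -> bool:
        m = self.mask(leaf_ids)
        if m == 0:
            raise ValidationError("empty leaf subset")
        return m in self.mask_set or (self.full ^ m) in self.mask_set

    def is_monophyletic_modulo(
        self, leaf_ids: Iterable[str], ignore_ids: Iterable[str]
    ) -> bool:
        """Monophyly after pruning ``ignore_ids`` from consideration: true
        iff some edge separates the subset from every non-ignored leaf."""
        core = self.mask(leaf_ids)
        ignore = self.mask(ignore_ids) if ignore_ids else 0
        keep = self.full ^ ignore
        if core == 0:
            raise ValidationError("empty leaf subset")
        for m in self.mask_set:
            if (m & keep) == core or ((self.full ^ m) & keep) == core:
                return True
        return False


def is_monophyletic(t: dendropy.Tree, leaf_subset: Iterable[str]) -> bool:
    """True iff the subset is separable by removing a single edge.

    Singletons are monophyletic by convention (their pendant edge).
    """
    return _TreeIndex(t).is_monophyletic(leaf_subset)


def haplotype_sharing(d: Dataset, min_comparable: int = 400) -> list[HaplotypePair]:
    """Cross-species pairs of specimens with identical barcode sequences.

    Identity is ambiguity-tolerant: the two sequences agree at every site
    where both carry an unambiguous base, and they share at least
    ``min_comparable`` such sites (the floor stops short fragments from
    "matching" everything).  Within-species identical haplotypes are normal
    and are not reported.
    """
    if len(d) < 2:
        return []
    enc = encode_sequences(d.sequences)
    sites, ndiff, _ = pairwise_counts(enc)
    species = np.array([r.binomial for r in d.records])
    cross = species[:, None] != species[None, :]
    identical = (ndiff == 0) & cross
    iu = np.triu_indices(len(d), 1)

    ok = identical[iu] & (sites[iu] >= min_comparable)
    short = identical[iu] & (sites[iu] < min_comparable) & (sites[iu] > 0)
    n_short = int(short.sum())
    if n_short:
        logger.info(
            "excluded %d cross-species identical pair(s) with fewer than %d "
            "comparable sites", n_short, min_comparable,
        )
    pairs = []
    ids = d.ids
    for i, j in zip(iu[0][ok], iu[1][ok]):
        pairs.append(
            HaplotypePair(ids[i], ids[j], str(species[i]), str(species[j]))
        )
    return pairs


def classify_species(
    t: dendropy.Tree,
    d: Dataset,
    outgroup_ids: set[str] | None = None,
    haplotype_floor: int = 400,
) -> list[SpeciesAssessment]:
    """Assign every species exactly one diagnosability condition.

    Decision cascade, per species S:

    1. one specimen and no cross-species identical haplotype
       -> SINGLETON_DISTINCT;
    2. monophyletic and no sharing -> DISTINCT;
    3. sharing, and S is still non-monophyletic after removing its
       specimens involved in cross-species identical haplotypes
       -> IDENTICAL_AND_OVERLAPPING;
    4. any other sharing -> IDENTICAL_SHARED;
    5. non-monophyletic without sharing: on the rooted view, take the MRCA
       of S's leaves and collect the other species with leaves inside it;
       exactly one such species, itself monophyletic -> PARAPHYLETIC;
       two or more -> POLYPHYLETIC; exactly one, mutually non-monophyletic
       -> OVERLAPPING.
    """
    members = d.species_members()
    tree_leaves = {lf.taxon.label for lf in t.leaf_node_iter()}
    ds_ids = set(d.ids)
    if tree_leaves != ds_ids:
        raise ValidationError(
            "tree leaves and dataset specimens differ: "
            f"only-tree={sorted(tree_leaves - ds_ids)[:5]}, "
            f"only-dataset={sorted(ds_ids - tree_leaves)[:5]}"
        )

    idx = _TreeIndex(t)
    pairs = haplotype_sharing(d, min_comparable=haplotype_floor)
    shares: dict[str, set[str]] = {}
    shared_specimens: dict[str, set[str]] = {}
    for p in pairs:
        shares.setdefault(p.species_a, set()).add(p.species_b)
        shares.setdefault(p.species_b, set()).add(p.species_a)
        shared_specimens.setdefault(p.species_a, set()).add(p.specimen_a)
        shared_specimens.setdefault(p.species_b, set()).add(p.specimen_b)

    if outgroup_ids:
        rooted = root_tree(t, outgroup_ids)
        logger.info("rooted on outgroup (%d leaves)", len(outgroup_ids))
    else:
        rooted = midpoint_root(t)
        logger.info("no outgroup given; midpoint rooting")
    taxon_of = {lf.taxon.label: lf.taxon for lf in rooted.leaf_node_iter()}
    species_of_id = {r.specimen_id: r.binomial for r in d.records}

    out: list[SpeciesAssessment] = []
    for sp, ids in members.items():
        partners = tuple(sorted(shares.get(sp, ())))
        mono = idx.is_monophyletic(ids)

        def inside_species() -> tuple[str, ...]:
            mrca = rooted.mrca(taxa=[taxon_of[s] for s in ids])
            inside = {species_of_id[lf.taxon.label] for lf in mrca.leaf_iter()}
            inside.discard(sp)
            return tuple(sorted(inside))

        if len(ids) == 1 and not partners:
            cond, congeners = Condition.SINGLETON_DISTINCT, ()
        elif mono and not partners:
            cond, congeners = Condition.DISTINCT, ()
        elif partners:
            # Overlap "beyond the shared haplotype itself": prune every
            # specimen involved in this species' sharing (on both sides of
            # each identical pair) and ask whether the remainder is still
            # non-monophyletic.
            core = [s for s in ids if s not in shared_specimens.get(sp, ())]
            ignore = set(shared_specimens.get(sp, set()))
            for other in partners:
                ignore |= shared_specimens.get(other, set())
            ignore -= set(core)
            if core and not idx.is_monophyletic_modulo(core, ignore):
                cond = Condition.IDENTICAL_AND_OVERLAPPING
                congeners = tuple(sorted(set(partners) | set(inside_species())))
            else:
                cond, congeners = Condition.IDENTICAL_SHARED, partners
        else:
            others = inside_species()
            if len(others) >= 2:
                cond, congeners = Condition.POLYPHYLETIC, others
            elif len(others) == 1:
                other = others[0]
                if idx.is_monophyletic(members[other]):
                    cond = Condition.PARAPHYLETIC
                else:
                    cond = Condition.OVERLAPPING
                congeners = others
            else:  # pragma: no cover - unreachable for a non-monophyletic set
                logger.warning("non-monophyletic %s has empty MRCA complement", sp)
                cond, congeners = Condition.OVERLAPPING, ()
        out.append(
            SpeciesAssessment(
                species=sp,
                n_specimens=len(ids),
                condition=cond,
                congeners_involved=congeners,
                shares_haplotype_with=partners,
            )
        )
    return out


def success_rate(assessments: Sequence[SpeciesAssessment]) -> tuple[int, int, float]:
    """(n_success, n_total, proportion) of diagnosable species."""
    if not assessments:
        raise ValidationError("no species assessments")
    n_success = sum(1 for a in assessments if a.success)
    n_total = len(assessments)
    return n_success, n_total, n_success / n_total


def condition_counts(assessments: Sequence[SpeciesAssessment]) -> dict[str, int]:
    counts = {c.value: 0 for c in Condition}
    for a in assessments:
        counts[a.condition.value] += 1
    return counts
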