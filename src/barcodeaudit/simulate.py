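"""Synthetic COI barcode communities with ground truth.

The generator emulates the statistical shape of a regional moth barcode
library: ~125 genera / ~400 species, 1-46 specimens per species (truncated
geometric, mean 6), 658 bp sequences, low intraspecific divergence
(target mean ~0.5%) far below congeneric interspecific divergence (target
mean ~9%), with an optional minority of species carrying engineered
diagnosability failures.  Every community ships with a truth table (the
condition each species was built to exhibit, its intraspecific cluster
structure, and which congeners share haplotypes) so the classification and
deep-split stages can be scored against known answers.

Sequences evolve under the Kimura 2-parameter substitution process
(independent sites, no indels; COI barcodes in these moths are
indel-free): per site, over a branch of expected length t substitutions
per site with transition/transversion rate ratio kappa, the replacement
probabilities are

    p_transition       = 1/4 + 1/4 exp(-4 b t) - 1/2 exp(-2 (a + b) t)
    p_each_transversion = 1/4 - 1/4 exp(-4 b t)

with a = kappa / (kappa + 2) and b = 1 / (kappa + 2) (so one expected
substitution event per site per unit t).  Pairwise K2P distances estimated
from the emitted sequences are therefore consistent for the generating
branch lengths.

Community layout: each genus gets an ancestor evolved from a global root;
species ancestors radiate star-like from the genus ancestor (no realistic
within-genus phylogeny, a documented simplification); specimens radiate
from the species ancestor with exponentially distributed tip branches.
Injections are applied last:

* ``shared_haplotype_pair`` - one specimen's sequence is copied verbatim
  onto a congener's specimen (both species become IDENTICAL_SHARED);
* ``paraphyly_pair``       - a congener's radiation is nested inside a
  species' own radiation (outer species PARAPHYLETIC, nested DISTINCT);
* ``deep_split_2`` / ``deep_split_3`` - a species' specimens split into
  2 or 3 subclusters whose ancestors sit > 3% expected divergence apart.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .discrimination import Condition
from .errors import ConfigError, ValidationError
from .records import Dataset, SpecimenRecord

_REGIONS = ("BC", "WA", "AB", "ID", "AK", "YT")
_REGION_P = (0.58, 0.12, 0.10, 0.08, 0.07, 0.05)
_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic community.

    Divergence targets are in percent K2P; branch-scale parameters
    (``genus_depth``, ``deep_split_branch`` ...) are expected substitutions
    per site.  Defaults mirror the structure of a comprehensive regional
    geometrid library.
    """

    n_genera: int = 125
    n_species: int = 400
    specimens_mean: float = 6.0
    specimens_max: int = 46
    seq_length: int = 658
    kappa: float = 4.0
    target_intra_pct: float = 0.5
    target_congeneric_pct: float = 9.0
    genus_depth: float = 0.06
    deep_split_branch: float = 0.03   # per-subcluster; between-cluster ~ 6%
    paraphyly_spread: float = 0.015   # outer species' internal split
    paraphyly_nested_depth: float = 0.012
    n_shared_haplotype_pairs: int = 0
    n_paraphyly_pairs: int = 0
    n_deep_split_2: int = 0
    n_deep_split_3: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genera < 1 or self.n_species < self.n_genera:
            raise ConfigError("need n_species >= n_genera >= 1")
        if self.specimens_mean < 1 or self.specimens_max < 1:
            raise ConfigError("specimen counts must be >= 1")
        if self.seq_length < 1:
            raise ConfigError("seq_length must be >= 1")
        if self.target_intra_pct <= 0 or self.target_congeneric_pct <= 0:
            raise ConfigError("divergence targets must be > 0")
        for f_ in ("n_shared_haplotype_pairs", "n_paraphyly_pairs",
                   "n_deep_split_2", "n_deep_split_3"):
            if getattr(self, f_) < 0:
                raise ConfigError(f"{f_} must be >= 0")


@dataclass(frozen=True)
class SpeciesTruth:
    """Ground truth for one simulated species."""

    species: str                    # binomial
    genus: str
    n_specimens: int
    condition: Condition
    cluster_sizes: tuple[int, ...]  # intraspecific subcluster sizes
    shares_with: tuple[str, ...] = ()
    paraphyletic_with: str | None = None   # nested congener, if any


@dataclass(frozen=True)
class SimTruth:
    """Truth table for a simulated community."""

    seed: int
    species: dict[str, SpeciesTruth]

    def injected(self) -> dict[str, SpeciesTruth]:
        """Species whose condition or cluster structure was engineered."""
        return {
            k: v
            for k, v in self.species.items()
            if v.condition is not Condition.DISTINCT
            or len(v.cluster_sizes) > 1
            or v.paraphyletic_with is not None
        }

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "species": {
                k: {**asdict(v), "condition": v.condition.value}
                for k, v in self.species.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _k2p_probs(t: float, kappa: float) -> tuple[float, float]:
    a = kappa / (kappa + 2.0)
    b = 1.0 / (kappa + 2.0)
    e1 = math.exp(-4.0 * b * t)
    e2 = math.exp(-2.0 * (a + b) * t)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1   # each of the two transversion targets
    return p_ts, p_tv


def _evolve(enc: np.ndarray, t: float, kappa: float, rng: np.random.Generator) -> np.ndarray:
    if t < 0:
        raise ValidationError("branch length must be >= 0")
    if t == 0:
        return enc.copy()
    p_ts, p_tv = _k2p_probs(t, kappa)
    u = rng.random(enc.size)
    out = enc.copy()
    out[u < p_ts] ^= 2
    out[(u >= p_ts) & (u < p_ts + p_tv)] ^= 1
    out[(u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)] ^= 3
    return out


def evolve_sequence(
    ancestor: str, branch_length: float, kappa: float, rng: np.random.Generator
) -> str:
    """Evolve a sequence along one branch of the K2P process.

    ``branch_length`` is in expected substitutions per site; the realized
    K2P distance to the ancestor is consistent for it.
    """
    enc = np.frombuffer(ancestor.encode("ascii"), dtype=np.uint8).copy()
    code = np.zeros(enc.size, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        code[enc == b] = i
    if not np.isin(enc, _ALPHABET).all():
        raise ValidationError("ancestor must be unambiguous A/C/G/T")
    return _decode(_evolve(code, branch_length, kappa, rng))


def _decode(code: np.ndarray) -> str:
    return _ALPHABET[code].tobytes().decode("ascii")


def _partition(n: int, k: int, rng: np.random.Generator) -> tuple[int, ...]:
    """Random composition of n into k parts, each >= 1."""
    extra = rng.multinomial(n - k, np.full(k, 1.0 / k))
    return tuple(int(x) + 1 for x in extra)


def simulate_community(cfg: SimConfig) -> tuple[Dataset, SimTruth]:
    """Generate a community and its ground truth. Deterministic per seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    L, kappa = cfg.seq_length, cfg.kappa

    # --- community layout -------------------------------------------------
    genus_of_species = list(range(cfg.n_genera))  # one species per genus
    genus_of_species += list(
        rng.integers(0, cfg.n_genera, size=cfg.n_species - cfg.n_genera)
    )
    genus_names = [f"Genus{g + 1:03d}" for g in range(cfg.n_genera)]
    species_names = [f"sp{s + 1:03d}" for s in range(cfg.n_species)]

    p_geom = min(1.0, 1.0 / cfg.specimens_mean)
    n_specimens = np.clip(
        rng.geometric(p_geom, size=cfg.n_species), 1, cfg.specimens_max
    ).astype(int)

    # --- injection planning ----------------------------------------------
    by_genus: dict[int, list[int]] = {}
    for s, g in enumerate(genus_of_species):
        by_genus.setdefault(g, []).append(s)
    multi_genera = [g for g, sps in by_genus.items() if len(sps) >= 2]
    rng.shuffle(multi_genera)

    used: set[int] = set()
    shared_pairs: list[tuple[int, int]] = []
    para_pairs: list[tuple[int, int]] = []   # (outer, nested)
    deep_splits: dict[int, int] = {}         # species -> k clusters

    def take_pair() -> tuple[int, int]:
        for g in multi_genera:
            free = [s for s in by_genus[g] if s not in used]
            if len(free) >= 2:
                a, b = free[0], free[1]
                used.update((a, b))
                return a, b
        raise ConfigError(
            "not enough genera with >= 2 uninjected species for the "
            "requested pair injections"
        )

    for _ in range(cfg.n_shared_haplotype_pairs):
        shared_pairs.append(take_pair())
    for _ in range(cfg.n_paraphyly_pairs):
        a, b = take_pair()
        n_specimens[a] = max(n_specimens[a], 4)
        n_specimens[b] = max(n_specimens[b], 2)
        para_pairs.append((a, b))
    singles = [s for s in range(cfg.n_species) if s not in used]
    rng.shuffle(singles)
    need = cfg.n_deep_split_2 + cfg.n_deep_split_3
    if len(singles) < need:
        raise ConfigError("not enough uninjected species for deep-split injections")
    for i in range(cfg.n_deep_split_2):
        s = singles[i]
        used.add(s)
        n_specimens[s] = max(n_specimens[s], 2)
        deep_splits[s] = 2
    for i in range(cfg.n_deep_split_3):
        s = singles[cfg.n_deep_split_2 + i]
        used.add(s)
        n_specimens[s] = max(n_specimens[s], 3)
        deep_splits[s] = 3

    # --- sequence generation ----------------------------------------------
    tip_mean = cfg.target_intra_pct / 200.0  # pairwise intra mean = 2 * tip
    sp_branch_mean = max(
        (cfg.target_congeneric_pct - cfg.target_intra_pct) / 200.0, 1e-4
    )
    global_root = rng.integers(0, 4, size=L).astype(np.uint8)
    genus_roots = [
        _evolve(global_root, cfg.genus_depth, kappa, rng) for g in range(cfg.n_genera)
    ]

    para_nested = {b: a for a, b in para_pairs}
    para_outer = {a: b for a, b in para_pairs}
    # species ancestors; nested species' ancestors are derived from the
    # outer species' internal node, so generate outer species first.
    anc: dict[int, np.ndarray] = {}
    x_node: dict[int, np.ndarray] = {}  # outer species' internal split node
    order = [s for s in range(cfg.n_species) if s not in para_nested]
    order += [s for s in range(cfg.n_species) if s in para_nested]
    for s in order:
        g = genus_of_species[s]
        if s in para_nested:
            outer = para_nested[s]
            anc[s] = _evolve(x_node[outer], cfg.paraphyly_nested_depth, kappa, rng)
        else:
            b_sp = rng.gamma(shape=3.0, scale=sp_branch_mean / 3.0)
            anc[s] = _evolve(genus_roots[g], b_sp, kappa, rng)
            if s in para_outer:
                x_node[s] = _evolve(anc[s], cfg.paraphyly_spread, kappa, rng)

    records: list[SpecimenRecord] = []
    truth: dict[str, SpeciesTruth] = {}
    first_specimen: dict[int, int] = {}   # species -> index into records
    counter = 0
    for s in range(cfg.n_species):
        g = genus_of_species[s]
        n = int(n_specimens[s])
        cluster_sizes: tuple[int, ...] = (n,)
        seqs: list[np.ndarray] = []
        if s in deep_splits:
            k = deep_splits[s]
            cluster_sizes = _partition(n, k, rng)
            for size in cluster_sizes:
                c_anc = _evolve(anc[s], cfg.deep_split_branch, kappa, rng)
                for _ in range(size):
                    seqs.append(_evolve(c_anc, rng.exponential(tip_mean), kappa, rng))
        elif s in para_outer:
            n1 = max(1, n // 2)
            for _ in range(n1):
                seqs.append(_evolve(anc[s], rng.exponential(tip_mean), kappa, rng))
            for _ in range(n - n1):
                seqs.append(_evolve(x_node[s], rng.exponential(tip_mean), kappa, rng))
        else:
            for _ in range(n):
                seqs.append(_evolve(anc[s], rng.exponential(tip_mean), kappa, rng))

        first_specimen[s] = len(records)
        binom = f"{genus_names[g]} {species_names[s]}"
        for seq in seqs:
            counter += 1
            records.append(
                SpecimenRecord(
                    specimen_id=f"SIM{counter:05d}",
                    genus=genus_names[g],
                    species=species_names[s],
                    region=str(rng.choice(_REGIONS, p=_REGION_P)),
                    sequence=_decode(seq),
                )
            )
        truth[binom] = SpeciesTruth(
            species=binom,
            genus=genus_names[g],
            n_specimens=n,
            condition=Condition.DISTINCT,
            cluster_sizes=cluster_sizes,
        )

    # --- apply haplotype copies and finalize truth labels -------------------
    def binom_of(s: int) -> str:
        return f"{genus_names[genus_of_species[s]]} {species_names[s]}"

    for a, b in shared_pairs:
        src = records[first_specimen[a]]
        dst_i = first_specimen[b]
        dst = records[dst_i]
        records[dst_i] = SpecimenRecord(
            specimen_id=dst.specimen_id,
            genus=dst.genus,
            species=dst.species,
            region=dst.region,
            sequence=src.sequence,
        )
        for s, other in ((a, b), (b, a)):
            old = truth[binom_of(s)]
            truth[binom_of(s)] = SpeciesTruth(
                species=old.species,
                genus=old.genus,
                n_specimens=old.n_specimens,
                condition=Condition.IDENTICAL_SHARED,
                cluster_sizes=old.cluster_sizes,
                shares_with=(binom_of(other),),
            )
    for a, b in para_pairs:
        old = truth[binom_of(a)]
        truth[binom_of(a)] = SpeciesTruth(
            species=old.species,
            genus=old.genus,
            n_specimens=old.n_specimens,
            condition=Condition.PARAPHYLETIC,
            cluster_sizes=old.cluster_sizes,
            paraphyletic_with=binom_of(b),
        )

    dataset = Dataset.from_records(records)
    return dataset, SimTruth(seed=cfg.seed, species=truth)
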