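"""Structured-coalescent generator for D-loop-like datasets.

The generator produces datasets with the statistical structure the analysis
assumes, so the whole pipeline is testable without any sequence download:

* five (by default) deep maternal clades standing in for haplogroups A-E,
  joined by a fixed pectinate spine so clade identity is unambiguous across
  seeds;
* breed-level substructure: within each breed (and haplogroup), lineages
  coalesce under a Kingman coalescent on a within-breed timescale, capped at
  ``split_depth``, after which surviving lineages enter their haplogroup's
  ancestral population;
* optional introgression pulses, modelled as discrete lineage
  re-assignment: a stated fraction of a recipient breed's lineages coalesce
  within the donor breed instead, giving an exact truth table;
* sequences evolved on the true genealogy under an HKY + gamma scheme:
  per-site rate multipliers from Gamma(shape, 1/shape), mutation events
  Poisson on branches at per-locus rate theta/2 per coalescent time unit
  (so the expected pairwise difference count for two lineages with
  E(T2) = 1 is theta), and an HKY one-step transition kernel.

Time is in coalescent units throughout; there is no explicit Ne or per-year
mutation rate, which keeps the closed-form expectations simple.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from dloopkin.io_formats import SequenceRecord, write_fasta, write_breed_table
from dloopkin.tree_model import write_newick

BASES = np.array(list("ACGT"))
#: AT-rich composition typical of the mammalian control region.
DEFAULT_BASE_FREQS = (0.32, 0.24, 0.14, 0.30)
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

HAPLOGROUP_NAMES = "ABCDEFGHIJ"


@dataclass(frozen=True)
class BreedSpec:
    """One simulated breed: name, sample size, haplogroup mixture weights."""

    name: str
    size: int
    haplogroup_weights: tuple[float, ...]
    region: str = "Egypt"
    tail: str = "thin"

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("breed size must be >= 1")
        w = np.asarray(self.haplogroup_weights, dtype=float)
        if w.min() < 0 or not math.isclose(w.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("haplogroup weights must be >= 0 and sum to 1")


@dataclass(frozen=True)
class IntrogressionPulse:
    """One-off transfer of a fraction of a recipient breed's maternal
    lineages into the donor breed's genealogy."""

    donor: str
    recipient: str
    fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("pulse fraction must be in [0, 1]")


@dataclass
class SimConfig:
    """Parameters of the generator.

    theta
        Per-locus population mutation rate (expected pairwise differences
        for a lineage pair with mean coalescence time 1).
    split_depth
        Time (coalescent units) at which breed lineages attach to their
        haplogroup's ancestral population; large relative to
        ``within_depth`` gives well-separated haplogroup clades.
    within_depth
        Timescale of the within-breed coalescent.
    """

    breeds: list[BreedSpec]
    n_haplogroups: int = 5
    theta: float = 5.0
    seq_length: int = 789
    split_depth: float = 5.0
    within_depth: float = 1.0
    spine_spacing: float = 5.0
    introgression_pulses: list[IntrogressionPulse] = field(default_factory=list)
    kappa: float = 10.0
    gamma_shape: float = 0.5
    base_freqs: tuple[float, float, float, float] = DEFAULT_BASE_FREQS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_haplogroups < 1 or self.n_haplogroups > len(HAPLOGROUP_NAMES):
            raise ValueError("n_haplogroups out of range")
        for b in self.breeds:
            if len(b.haplogroup_weights) != self.n_haplogroups:
                raise ValueError(
                    f"breed {b.name}: weight vector length must equal "
                    f"n_haplogroups ({self.n_haplogroups})"
                )
        names = [b.name for b in self.breeds]
        if len(set(names)) != len(names):
            raise ValueError("breed names must be unique")

    def haplogroup_names(self) -> list[str]:
        return list(HAPLOGROUP_NAMES[: self.n_haplogroups])


@dataclass
class SimResult:
    """Alignment, breed table, true genealogy and truth table of one run."""

    records: list[SequenceRecord]
    breed_table: pd.DataFrame
    genealogy: dendropy.Tree
    truth: pd.DataFrame  # id, breed, haplogroup, introgressed, donor

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.records, out / "alignment.fasta")
        write_breed_table(self.breed_table, out / "breeds.tsv")
        write_newick(self.genealogy, out / "genealogy.nwk")
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)


class _Lineage:
    __slots__ = ("node", "time")

    def __init__(self, node: dendropy.Node, time: float):
        self.node = node
        self.time = time


def _coalesce_pair(a: _Lineage, b: _Lineage, t: float) -> _Lineage:
    parent = dendropy.Node()
    for child in (a, b):
        parent.add_child(child.node)
        child.node.edge.length = t - child.time
    return _Lineage(parent, t)


def simulate_genealogy(
    config: SimConfig, seed: int | None = None
) -> tuple[dendropy.Tree, pd.DataFrame]:
    """Simulate the true genealogy and its truth table.

    Returns a rooted ultrametric tree (branch lengths in coalescent units;
    tips named ``<breed>_<k>``) and a table with one row per tip: breed,
    true haplogroup, whether the lineage was moved by a pulse, and its
    donor breed if so.  Fully reproducible from the seed.
    """
    if seed is None:
        seed = config.seed
    ss = np.random.SeedSequence(seed)
    rng_assign, rng_pulse, rng_coal = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )
    haps = config.haplogroup_names()

    taxon_ns = dendropy.TaxonNamespace()
    tip_breed: dict[str, str] = {}
    coal_breed: dict[str, str] = {}  # breed whose genealogy the tip joins
    tip_hap: dict[str, str] = {}
    moved: dict[str, str] = {}  # tip -> donor breed
    by_breed_tips: dict[str, list[str]] = {}

    for breed in config.breeds:
        tips = [f"{breed.name}_{k + 1}" for k in range(breed.size)]
        by_breed_tips[breed.name] = tips
        draws = rng_assign.choice(haps, size=breed.size, p=breed.haplogroup_weights)
        for tip, h in zip(tips, draws):
            tip_breed[tip] = breed.name
            coal_breed[tip] = breed.name
            tip_hap[tip] = str(h)

    breed_by_name = {b.name: b for b in config.breeds}
    for pulse in config.introgression_pulses:
        if pulse.donor not in breed_by_name or pulse.recipient not in breed_by_name:
            raise KeyError(f"pulse names unknown breed: {pulse}")
        if pulse.fraction == 0.0:
            continue
        rec = breed_by_name[pulse.recipient]
        n_moved = max(1, round(pulse.fraction * rec.size))
        if n_moved >= rec.size:
            raise ValueError(
                f"pulse {pulse.donor}->{pulse.recipient}: {n_moved} moved "
                f"lineages would empty the recipient (size {rec.size})"
            )
        eligible = [
            t for t in by_breed_tips[pulse.recipient] if t not in moved
        ]
        chosen = rng_pulse.choice(eligible, size=n_moved, replace=False)
        donor_spec = breed_by_name[pulse.donor]
        for tip in chosen:
            moved[tip] = pulse.donor
            coal_breed[tip] = pulse.donor
            tip_hap[tip] = str(
                rng_pulse.choice(haps, p=donor_spec.haplogroup_weights)
            )

    # within-(breed, haplogroup) Kingman coalescence, capped at split_depth
    survivors: dict[str, list[_Lineage]] = {h: [] for h in haps}
    groups: dict[tuple[str, str], list[str]] = {}
    for tip in tip_breed:
        groups.setdefault((coal_breed[tip], tip_hap[tip]), []).append(tip)
    for (breed_name, hap) in sorted(groups):
        lineages = []
        for tip in sorted(groups[(breed_name, hap)]):
            node = dendropy.Node()
            node.taxon = taxon_ns.require_taxon(label=tip)
            lineages.append(_Lineage(node, 0.0))
        t = 0.0
        while len(lineages) > 1:
            k = len(lineages)
            rate = k * (k - 1) / 2.0 / config.within_depth
            t += rng_coal.exponential(1.0 / rate)
            if t > config.split_depth:
                break
            i, j = sorted(rng_coal.choice(k, size=2, replace=False))
            b = lineages.pop(j)
            a = lineages.pop(i)
            lineages.append(_coalesce_pair(a, b, t))
        survivors[hap].extend(lineages)

    # haplogroup ancestral populations from split_depth
    hap_roots: dict[str, _Lineage] = {}
    for hap in haps:
        lineages = survivors[hap]
        if not lineages:
            continue
        t = config.split_depth
        while len(lineages) > 1:
            k = len(lineages)
            t += rng_coal.exponential(2.0 / (k * (k - 1)))
            i, j = sorted(rng_coal.choice(k, size=2, replace=False))
            b = lineages.pop(j)
            a = lineages.pop(i)
            lineages.append(_coalesce_pair(a, b, t))
        hap_roots[hap] = lineages[0]

    # fixed pectinate spine over the haplogroup ancestors
    present = [h for h in haps if h in hap_roots]
    if not present:
        raise ValueError("no lineages simulated")
    spine = hap_roots[present[0]]
    t_join = max(hap_roots[h].time for h in present) + config.spine_spacing
    for h in present[1:]:
        spine = _coalesce_pair(spine, hap_roots[h], t_join)
        t_join += config.spine_spacing

    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.seed_node = spine.node
    tree.is_rooted = True
    tree.seed_node.edge.length = None

    truth = pd.DataFrame(
        {
            "id": list(tip_breed),
            "breed": [tip_breed[t] for t in tip_breed],
            "haplogroup": [tip_hap[t] for t in tip_breed],
            "introgressed": [t in moved for t in tip_breed],
            "donor": [moved.get(t, "") for t in tip_breed],
        }
    )
    return tree, truth


def mutate_hky_gamma(
    genealogy: dendropy.Tree,
    theta: float,
    kappa: float = 10.0,
    gamma_shape: float = 0.5,
    seq_length: int = 789,
    seed: int = 0,
    base_freqs: tuple[float, float, float, float] = DEFAULT_BASE_FREQS,
) -> dict[str, str]:
    """Evolve sequences down a genealogy with branch lengths.

    Site rate multipliers are Gamma(shape, 1/shape) (mean 1); mutation
    events are Poisson on each branch with per-locus rate theta/2 per unit
    time; each event picks a site proportionally to its rate and applies an
    HKY one-step kernel (target base probability proportional to its
    stationary frequency, times kappa for transitions).  Returns tip id ->
    sequence.  theta = 0 yields identical sequences.
    """
    rng = np.random.default_rng(seed)
    pi = np.asarray(base_freqs, dtype=float)
    if not math.isclose(pi.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("base frequencies must sum to 1")
    rates = (
        rng.gamma(gamma_shape, 1.0 / gamma_shape, size=seq_length)
        if gamma_shape > 0
        else np.ones(seq_length)
    )
    site_p = rates / rates.sum()

    # one-step HKY kernels, one per source base
    kernels = {}
    for i, src in enumerate("ACGT"):
        w = pi.copy()
        w[i] = 0.0
        tsi = "ACGT".index(_TRANSITION[src])
        w[tsi] *= kappa
        kernels[src] = w / w.sum()

    root_seq = rng.choice(BASES, size=seq_length, p=pi)
    seqs: dict[str, str] = {}

    def descend(node: dendropy.Node, seq: np.ndarray) -> None:
        for child in node.child_nodes():
            length = child.edge.length
            if length is None:
                raise ValueError("genealogy branch lacks a length")
            child_seq = seq.copy()
            n_mut = rng.poisson(length * theta / 2.0) if theta > 0 else 0
            if n_mut:
                sites = rng.choice(seq_length, size=n_mut, p=site_p)
                for s in sites:
                    child_seq[s] = rng.choice(BASES, p=kernels[child_seq[s]])
            if child.is_leaf():
                seqs[child.taxon.label] = "".join(child_seq)
            else:
                descend(child, child_seq)

    descend(genealogy.seed_node, root_seq)
    return seqs


def simulate_dataset(config: SimConfig, seed: int | None = None) -> SimResult:
    """Run the full generator: genealogy, truth table, mutated alignment and
    breed table, all consistent tip-by-tip."""
    if seed is None:
        seed = config.seed
    genealogy, truth = simulate_genealogy(config, seed=seed)
    mut_seed = int(
        np.random.SeedSequence(seed).spawn(4)[3].generate_state(1)[0] % (2**31)
    )
    seqs = mutate_hky_gamma(
        genealogy,
        theta=config.theta,
        kappa=config.kappa,
        gamma_shape=config.gamma_shape,
        seq_length=config.seq_length,
        seed=mut_seed,
        base_freqs=config.base_freqs,
    )
    meta = {b.name: b for b in config.breeds}
    records = [
        SequenceRecord(
            id=row.id,
            sequence=seqs[row.id],
            breed=row.breed,
            region=meta[row.breed].region,
        )
        for row in truth.itertuples()
    ]
    table = pd.DataFrame(
        {
            "id": truth["id"],
            "breed": truth["breed"],
            "region": [meta[b].region for b in truth["breed"]],
            "tail": [meta[b].tail for b in truth["breed"]],
        }
    )
    return SimResult(
        records=records, breed_table=table, genealogy=genealogy, truth=truth
    )


def random_binary_tree(n_tips: int, seed: int = 0) -> dendropy.Tree:
    """Uniform random coalescent topology with tips T1..Tn (unit branches)."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    taxon_ns = dendropy.TaxonNamespace()
    active: list[dendropy.Node] = []
    for k in range(n_tips):
        node = dendropy.Node()
        node.taxon = taxon_ns.require_taxon(label=f"T{k + 1}")
        active.append(node)
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        b = active.pop(j)
        a = active.pop(i)
        parent = dendropy.Node()
        for child in (a, b):
            parent.add_child(child)
            child.edge.length = 1.0
        active.append(parent)
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.seed_node = active[0]
    tree.is_rooted = True
    return tree
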