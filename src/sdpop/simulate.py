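"""Synthetic-data generators: coalescent haplotypes, copy-number genotypes,
and duplicated sequence pairs with planted gene-conversion tracts.

The coalescent simulator implements the standard structured coalescent
with piecewise-exponential population sizes, population splits (viewed
backwards as lineage mergers), backwards migration, and ancient (non-zero
time) sampling — enough to emulate constant-size, split, growth and
archaic-sampling demographies at the single-window scale. Each simulated
window is one non-recombining genealogy; windows are independent. Mutations
follow the infinite-sites model: Poisson(total branch length × μ × L)
mutations dropped on branches proportionally to branch length, each at a
unique integer position in [0, L).

Time is measured in generations throughout; conversion to years happens
only at reporting time via ``generation_time``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from .popgen import HaplotypeMatrix

__all__ = [
    "Population",
    "DemographicEvent",
    "SampleGroup",
    "DemographicModel",
    "SimulatedReplicate",
    "CNAlleleModel",
    "ModelValidationError",
    "simulate_coalescent",
    "simulate_two_group_model",
    "simulate_cn_genotypes",
    "simulate_star_genealogy",
    "plant_igc",
]


class ModelValidationError(ValueError):
    """A demographic model is internally inconsistent."""


@dataclass(frozen=True)
class Population:
    name: str
    size: float  # diploid effective size N_e
    growth_rate: float = 0.0  # forward per-generation exponential rate


@dataclass(frozen=True)
class DemographicEvent:
    """A scheduled change in the demography at ``time`` generations ago.

    kind 'split': population ``derived`` merges (backwards) into
    ``ancestral``. kind 'size_change': ``population`` takes a new
    ``size`` and ``growth_rate``. kind 'migration_change': the backwards
    migration rate ``source`` → ``dest`` becomes ``rate`` per lineage
    per generation.
    """

    time: float
    kind: str
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class SampleGroup:
    population: str
    n: int
    time: float = 0.0  # generations before present


@dataclass
class DemographicModel:
    populations: list
    samples: list
    events: list = field(default_factory=list)
    mutation_rate: float = 1.25e-8
    recombination_rate: float = 0.0
    generation_time: float = 29.0

    def __post_init__(self):
        self.events = sorted(self.events, key=lambda e: e.time)
        self.validate()

    def validate(self) -> None:
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ModelValidationError("duplicate population names")
        if not self.samples:
            raise ModelValidationError("at least one sample group required")
        for p in self.populations:
            if p.size <= 0:
                raise ModelValidationError(f"population {p.name}: size must be > 0")
        if self.mutation_rate <= 0:
            raise ModelValidationError("mutation_rate must be > 0")
        terminal = {n: math.inf for n in names}
        merged: set[str] = set()
        parent = {n: n for n in names}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        has_migration = False
        for ev in self.events:
            if ev.time < 0:
                raise ModelValidationError(f"event {ev.kind}: negative time {ev.time}")
            if ev.kind == "split":
                der, anc = ev.params.get("derived"), ev.params.get("ancestral")
                if der not in terminal or anc not in terminal:
                    raise ModelValidationError(
                        f"split at t={ev.time}: unknown population {der!r} or {anc!r}")
                if der in merged:
                    raise ModelValidationError(
                        f"split at t={ev.time}: {der} already merged")
                merged.add(der)
                terminal[der] = ev.time
                parent[find(der)] = find(anc)
            elif ev.kind == "size_change":
                if ev.params.get("population") not in terminal:
                    raise ModelValidationError(
                        f"size_change at t={ev.time}: unknown population")
                if ev.params.get("size", 1.0) <= 0:
                    raise ModelValidationError(
                        f"size_change at t={ev.time}: size must be > 0")
            elif ev.kind == "migration_change":
                has_migration = True
                if (ev.params.get("source") not in terminal
                        or ev.params.get("dest") not in terminal):
                    raise ModelValidationError(
                        f"migration_change at t={ev.time}: unknown population")
                if ev.params.get("rate", 0.0) < 0:
                    raise ModelValidationError(
                        f"migration_change at t={ev.time}: negative rate")
            else:
                raise ModelValidationError(f"unknown event kind {ev.kind!r}")
        if len(names) > 1 and not has_migration:
            roots = {find(n) for n in names}
            if len(roots) > 1:
                raise ModelValidationError(
                    "population tree implied by splits is not connected: "
                    + ", ".join(sorted(roots)))
        for s in self.samples:
            if s.population not in terminal:
                raise ModelValidationError(f"sample from unknown population {s.population}")
            if s.n < 0:
                raise ModelValidationError("sample size must be non-negative")
            if s.time < 0:
                raise ModelValidationError("sampling time must be non-negative")
            if s.time >= terminal[s.population]:
                raise ModelValidationError(
                    f"sampling time {s.time} not before terminal time of {s.population}")

    @classmethod
    def constant(cls, n_e, n_samples, mutation_rate=1.25e-8, generation_time=29.0,
                 name="pop0"):
        """Single constant-size population, present-day sampling."""
        return cls(
            populations=[Population(name, n_e)],
            samples=[SampleGroup(name, n_samples)],
            mutation_rate=mutation_rate,
            generation_time=generation_time,
        )

    @classmethod
    def two_group(cls, n_e_modern, n_e_archaic, n_e_ancestral, split_time,
                  archaic_sampling_time, n_modern, n_archaic,
                  mutation_rate=1.25e-8, generation_time=29.0):
        """Modern + archaic-style split model with ancient sampling."""
        return cls(
            populations=[
                Population("modern", n_e_modern),
                Population("archaic", n_e_archaic),
            ],
            samples=[
                SampleGroup("modern", n_modern, 0.0),
                SampleGroup("archaic", n_archaic, archaic_sampling_time),
            ],
            events=[
                DemographicEvent(split_time, "split",
                                 {"derived": "archaic", "ancestral": "modern"}),
                DemographicEvent(split_time, "size_change",
                                 {"population": "modern", "size": n_e_ancestral,
                                  "growth_rate": 0.0}),
            ],
            mutation_rate=mutation_rate,
            generation_time=generation_time,
        )

    @classmethod
    def from_config(cls, path):
        """Load a model from a YAML key/value config file."""
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        pops = [Population(p["name"], float(p["size"]),
                           float(p.get("growth_rate", 0.0)))
                for p in cfg["populations"]]
        samples = [SampleGroup(s["population"], int(s["n"]),
                               float(s.get("time", 0.0)))
                   for s in cfg["samples"]]
        events = []
        for ev in cfg.get("events", []):
            params = {k: v for k, v in ev.items() if k not in ("time", "kind")}
            events.append(DemographicEvent(float(ev["time"]), ev["kind"], params))
        return cls(
            populations=pops,
            samples=samples,
            events=events,
            mutation_rate=float(cfg.get("mutation_rate", 1.25e-8)),
            recombination_rate=float(cfg.get("recombination_rate", 0.0)),
            generation_time=float(cfg.get("generation_time", 29.0)),
        )


@dataclass
class SimulatedReplicate:
    haplotypes: HaplotypeMatrix
    tmrca: float  # generations
    tree: str | None = None  # newick


# ---------------------------------------------------------------------------
# the coalescent engine


class _PopState:
    __slots__ = ("size", "growth", "ref_time")

    def __init__(self, size, growth, ref_time=0.0):
        self.size = size      # diploid N_e at ref_time
        self.growth = growth  # forward growth rate
        self.ref_time = ref_time

    def size_at(self, t):
        # backwards: N(t) = N(ref) * exp(-g * (t - ref))
        return self.size * math.exp(-self.growth * (t - self.ref_time))


def _coal_wait(k, n_now, growth, rng):
    """Waiting time to the next coalescence among k lineages.

    Population size N(s) = n_now * exp(-growth*s) looking further back.
    Uses inverse integrated hazard; returns inf when the cumulative
    hazard is bounded below the exponential draw (declining backwards
    size never reached).
    """
    if k < 2:
        return math.inf
    base = k * (k - 1) / 2.0 / (2.0 * n_now)
    e = rng.exponential()
    if growth == 0.0:
        return e / base
    arg = 1.0 + growth * e / base
    if arg <= 0:
        return math.inf
    return math.log(arg) / growth


def simulate_coalescent(model: DemographicModel, sequence_length, seed,
                        with_tree=False):
    """Simulate one non-recombining genealogy and drop infinite-sites mutations.

    Returns a :class:`SimulatedReplicate` whose haplotype matrix is
    derived-allele encoded (polarized by construction: the simulator
    knows the ancestral state). Deterministic given ``seed``.
    """
    if sequence_length <= 0:
        raise ValueError("sequence_length must be positive")
    model.validate()
    rng = np.random.default_rng(seed)

    # node bookkeeping
    node_time: list[float] = []
    node_children: list[tuple] = []
    leaf_ids = []
    leaf_pops = []

    pending = []  # (time, population, node_id)
    for grp in model.samples:
        for _ in range(grp.n):
            nid = len(node_time)
            node_time.append(grp.time)
            node_children.append(())
            leaf_ids.append(nid)
            leaf_pops.append(grp.population)
            pending.append((grp.time, grp.population, nid))
    pending.sort(key=lambda x: x[0])
    n_leaves = len(leaf_ids)

    pops = {p.name: _PopState(p.size, p.growth_rate) for p in model.populations}
    lineages = {p.name: [] for p in model.populations}
    migration = {}  # (source, dest) -> rate
    events = list(model.events)  # sorted by time
    ev_idx = 0
    t = 0.0
    root = pending[0][2] if n_leaves == 1 else None

    def n_active():
        return sum(len(v) for v in lineages.values())

    while pending or n_active() > 1:
        # next deterministic event time
        t_fixed = math.inf
        if pending:
            t_fixed = min(t_fixed, pending[0][0])
        if ev_idx < len(events):
            t_fixed = min(t_fixed, events[ev_idx].time)

        # candidate stochastic waits
        best_wait = math.inf
        best_action = None
        for name, lin in lineages.items():
            st = pops[name]
            w = _coal_wait(len(lin), st.size_at(t), st.growth, rng)
            if w < best_wait:
                best_wait = w
                best_action = ("coal", name)
        mig_rate = 0.0
        mig_choices = []
        for (src, dst), rate in migration.items():
            r = rate * len(lineages[src])
            if r > 0:
                mig_rate += r
                mig_choices.append((r, src, dst))
        if mig_rate > 0:
            w = rng.exponential() / mig_rate
            if w < best_wait:
                best_wait = w
                best_action = ("mig", None)

        if t + best_wait < t_fixed:
            t = t + best_wait
            if best_action[0] == "coal":
                name = best_action[1]
                lin = lineages[name]
                i, j = rng.choice(len(lin), size=2, replace=False)
                a, b = lin[int(i)], lin[int(j)]
                nid = len(node_time)
                node_time.append(t)
                node_children.append((a, b))
                lineages[name] = [x for x in lin if x not in (a, b)] + [nid]
                root = nid
            else:
                u = rng.uniform(0, mig_rate)
                acc = 0.0
                for r, src, dst in mig_choices:
                    acc += r
                    if u <= acc:
                        lin = lineages[src]
                        k = int(rng.integers(len(lin)))
                        lineages[dst].append(lin.pop(k))
                        break
            continue

        if not math.isfinite(t_fixed):
            raise ModelValidationError(
                "simulation cannot proceed: multiple lineages remain with no "
                "coalescence possible (check splits/migration)")
        t = t_fixed
        while pending and pending[0][0] <= t:
            _, popname, nid = pending.pop(0)
            lineages[popname].append(nid)
        while ev_idx < len(events) and events[ev_idx].time <= t:
            ev = events[ev_idx]
            ev_idx += 1
            if ev.kind == "split":
                der, anc = ev.params["derived"], ev.params["ancestral"]
                lineages[anc].extend(lineages[der])
                lineages[der] = []
                # derived population ceases to exist backwards in time
                pops[der] = _PopState(pops[der].size_at(t), 0.0, t)
                migration = {k: v for k, v in migration.items()
                             if der not in k}
            elif ev.kind == "size_change":
                name = ev.params["population"]
                pops[name] = _PopState(
                    float(ev.params["size"]),
                    float(ev.params.get("growth_rate", 0.0)),
                    t,
                )
            elif ev.kind == "migration_change":
                migration[(ev.params["source"], ev.params["dest"])] = float(
                    ev.params["rate"])

    tmrca = 0.0 if n_leaves == 1 else node_time[root] - min(
        node_time[i] for i in leaf_ids)
    # place mutations
    n_nodes = len(node_time)
    parent_of = np.full(n_nodes, -1, dtype=np.int64)
    for nid, children in enumerate(node_children):
        for c in children:
            parent_of[c] = nid
    blen = np.zeros(n_nodes)
    for nid in range(n_nodes):
        p = parent_of[nid]
        if p >= 0:
            blen[nid] = node_time[p] - node_time[nid]
    total_len = blen.sum()
    n_mut = rng.poisson(total_len * model.mutation_rate * sequence_length)

    # leaves below each node
    below = [None] * n_nodes
    for nid in range(n_nodes):  # children always have lower ids
        if not node_children[nid]:
            below[nid] = [nid]
        else:
            acc = []
            for c in node_children[nid]:
                acc.extend(below[c])
            below[nid] = acc
    leaf_index = {nid: i for i, nid in enumerate(leaf_ids)}

    positions = []
    carriers = []
    used = set()
    if n_mut > 0 and total_len > 0:
        branch_ids = rng.choice(n_nodes, size=n_mut, p=blen / total_len)
        for b in branch_ids:
            pos = int(rng.integers(0, sequence_length))
            while pos in used:  # infinite sites: unique integer positions
                pos = int(rng.integers(0, sequence_length))
            used.add(pos)
            positions.append(pos)
            carriers.append([leaf_index[x] for x in below[int(b)]])
    order = np.argsort(positions) if positions else np.array([], dtype=int)
    data = np.zeros((n_leaves, len(positions)), dtype=np.int8)
    for col, k in enumerate(order):
        data[carriers[int(k)], col] = 1
    pos_sorted = np.array([positions[int(k)] for k in order], dtype=np.int64) + 1

    matrix = HaplotypeMatrix(
        data, pos_sorted, chrom="sim",
        populations=np.array(leaf_pops, dtype=object),
        polarized=True,
    )
    newick = _to_newick(node_children, node_time, root, leaf_ids, leaf_pops) \
        if with_tree and root is not None else None
    return SimulatedReplicate(matrix, float(tmrca), newick)


def _to_newick(children, times, root, leaf_ids, leaf_pops):
    labels = {nid: f"{leaf_pops[i]}_{i}" for i, nid in enumerate(leaf_ids)}

    def rec(nid):
        if not children[nid]:
            return labels[nid]
        parts = ",".join(
            f"{rec(c)}:{times[nid] - times[c]:.6f}" for c in children[nid])
        return f"({parts})"

    return rec(root) + ";"


def simulate_two_group_model(model: DemographicModel, sequence_length, seed,
                             with_tree=False):
    """Simulate under a two-group (modern/archaic-style) model.

    Thin wrapper over :func:`simulate_coalescent` that additionally
    checks the ancient-sampling precondition: at least one sample group
    must be sampled at a time > 0 generations before present.
    """
    if not any(s.time > 0 for s in model.samples):
        raise ModelValidationError(
            "two-group model requires an ancient (time > 0) sample group")
    return simulate_coalescent(model, sequence_length, seed, with_tree=with_tree)


def simulate_star_genealogy(n, branch_length, mutation_rate, sequence_length,
                            seed, population="pop0"):
    """Star genealogy toy: n lineages all coalescing at one point.

    Emulates the extreme post-sweep genealogy (complete hitchhiking):
    every mutation is a singleton, giving strongly negative Tajima's D.
    Used as a directional power control, not a model of real sweeps.
    """
    rng = np.random.default_rng(seed)
    positions = []
    carriers = []
    used = set()
    n_mut = rng.poisson(n * branch_length * mutation_rate * sequence_length)
    for _ in range(n_mut):
        pos = int(rng.integers(0, sequence_length))
        while pos in used:
            pos = int(rng.integers(0, sequence_length))
        used.add(pos)
        positions.append(pos)
        carriers.append(int(rng.integers(0, n)))
    order = np.argsort(positions) if positions else np.array([], dtype=int)
    data = np.zeros((n, len(positions)), dtype=np.int8)
    for col, k in enumerate(order):
        data[carriers[int(k)], col] = 1
    pos_sorted = np.array([positions[int(k)] for k in order], dtype=np.int64) + 1
    matrix = HaplotypeMatrix(data, pos_sorted, chrom="star",
                             populations=np.array([population] * n, dtype=object))
    return SimulatedReplicate(matrix, float(branch_length), None)


# ---------------------------------------------------------------------------
# copy-number genotypes


@dataclass
class CNAlleleModel:
    """Haploid cassette-count allele frequencies per population.

    ``classes`` maps population name → {cassette count (int ≥ 0): frequency}.
    Frequencies must sum to 1 per population.
    """

    classes: dict

    def __post_init__(self):
        for pop, freqs in self.classes.items():
            if not freqs:
                raise ValueError(f"population {pop}: empty haploid class map")
            if any(k < 0 for k in freqs):
                raise ValueError(f"population {pop}: negative cassette count")
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"population {pop}: haploid frequencies sum to {total}, not 1")


def simulate_cn_genotypes(allele_model: CNAlleleModel, n_samples, seed):
    """Draw diploid copy-number genotypes from haploid cassette-count alleles.

    Each diploid CN is the sum of two independently drawn haploid
    classes. ``n_samples`` is either an int (every population) or a
    mapping population → count. Returns a :class:`sdpop.cn.CNMatrix`
    with a single locus column.
    """
    from .cn import CNMatrix

    rng = np.random.default_rng(seed)
    values = []
    labels = []
    samples = []
    for pop, freqs in allele_model.classes.items():
        n = n_samples[pop] if isinstance(n_samples, dict) else n_samples
        ks = np.array(sorted(freqs))
        ps = np.array([freqs[k] for k in ks], dtype=float)
        ps = ps / ps.sum()
        diploid = rng.choice(ks, size=n, p=ps) + rng.choice(ks, size=n, p=ps)
        values.extend(diploid.astype(float))
        labels.extend([pop] * n)
        samples.extend(f"{pop}_{i}" for i in range(n))
    return CNMatrix(
        values=np.asarray(values, dtype=float).reshape(-1, 1),
        samples=np.array(samples, dtype=object),
        populations=np.array(labels, dtype=object),
        loci=[("locus0", 1, 1000)],
    )


# ---------------------------------------------------------------------------
# gene-conversion fixture


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def plant_igc(seq_length, divergence, tract, seed):
    """Build an aligned duplicate pair with a planted gene-conversion tract.

    Outside ``tract`` (0-based half-open) mismatches are placed i.i.d. at
    rate ``divergence``; inside it the two sequences are identical —
    emulating a recent interlocus gene-conversion event homogenizing the
    acceptor to the donor.

    Returns ``(donor, acceptor, (start, end))`` with the truth tract for
    recovery tests.
    """
    start, end = tract
    if not (0 <= start <= end <= seq_length):
        raise ValueError(f"tract {tract} outside sequence of length {seq_length}")
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must be in [0, 1]")
    rng = np.random.default_rng(seed)
    donor_idx = rng.integers(0, 4, size=seq_length)
    acceptor_idx = donor_idx.copy()
    mismatch = rng.random(seq_length) < divergence
    mismatch[start:end] = False
    # substitute with a different base at mismatch sites
    shift = rng.integers(1, 4, size=seq_length)
    acceptor_idx[mismatch] = (acceptor_idx[mismatch] + shift[mismatch]) % 4
    donor = _BASES[donor_idx].tobytes().decode()
    acceptor = _BASES[acceptor_idx].tobytes().decode()
    return donor, acceptor, (int(start), int(end))
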