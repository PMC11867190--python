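"""Forward simulation of PBD and (piecewise-constant) BD processes.

The PBD simulator is an exact Gillespie algorithm over the five per-lineage
rates; it records the complete event history (:class:`~pbdrates.trees.FullTree`)
from which the reconstructed tree of extant good species is extracted.
Species identity follows the label convention: an incipient lineage is
conspecific with its parent until it completes speciation, at which point it
founds a new species; a species is extant if any member lineage survives to
the present (its completed founder may itself be dead — incipient members
buffer species extinction).

The BD simulator handles arbitrary piecewise-constant birth/death rates,
which is how the equivalent time-varying rate trajectory is simulated, and
conditions on a minimum number of surviving lineages by retrying.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import dendropy
import numpy as np
import pandas as pd

from .params import PBDParams, SimulationConfig
from .rates import (
    PiecewiseConstantRates,
    discretize_trajectory,
    equivalent_constant_rates,
    equivalent_rate_trajectory,
)
from .trees import FullTree, LineageRecord, ReconstructedTree

#: Abort a replicate whose standing lineage count exceeds this cap
#: (protects parameter sweeps from supercritical blow-up).
MAX_LINEAGES = 10**6


class SimulationExplosion(RuntimeError):
    """Raised when a replicate exceeds the standing-lineage cap."""


def simulate_pbd(params: PBDParams, config: SimulationConfig, rng=None) -> FullTree:
    """Exact Gillespie simulation of the PBD process on ``[0, T]``.

    Starts from a single good stem lineage at time 0.  Total event rate is
    ``n_good * (lambda1 + mu1) + n_incipient * (lambda2 + lambda3 + mu2)``;
    waiting times are exponential and the event/lineage are chosen
    proportionally to their rates.  Stops at ``T`` or on total extinction.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    l1, l2, l3 = params.lambda1, params.lambda2, params.lambda3
    m1, m2 = params.mu1, params.mu2
    Theta, Lam = params.Theta, params.Lambda
    T = config.T

    records: list[LineageRecord] = [LineageRecord(id=0, parent=None, birth=0.0, species=1, completion=0.0)]
    next_species = 2
    good: list[int] = [0]       # indices into records
    incipient: list[int] = []
    t = 0.0

    def _remove(pool: list[int], pos: int) -> None:
        pool[pos] = pool[-1]
        pool.pop()

    while good or incipient:
        total = len(good) * Theta + len(incipient) * Lam
        if total <= 0:
            break
        t += rng.exponential(1.0 / total)
        if t >= T:
            break
        u = rng.uniform(0.0, total)
        if u < len(good) * Theta:
            # event on a good lineage
            pos = int(u // Theta)
            lineage = good[pos]
            if (u - pos * Theta) < l1:
                records.append(
                    LineageRecord(
                        id=len(records),
                        parent=lineage,
                        birth=t,
                        species=records[lineage].species,
                    )
                )
                incipient.append(len(records) - 1)
            else:
                records[lineage].death = t
                _remove(good, pos)
        else:
            u -= len(good) * Theta
            pos = int(u // Lam)
            lineage = incipient[pos]
            r = u - pos * Lam
            if r < l2:
                rec = records[lineage]
                rec.completion = t
                rec.species = next_species
                next_species += 1
                _remove(incipient, pos)
                good.append(lineage)
            elif r < l2 + l3:
                records.append(
                    LineageRecord(
                        id=len(records),
                        parent=lineage,
                        birth=t,
                        species=records[lineage].species,
                    )
                )
                incipient.append(len(records) - 1)
            else:
                records[lineage].death = t
                _remove(incipient, pos)
        if len(good) + len(incipient) > MAX_LINEAGES:
            raise SimulationExplosion(
                f"replicate exceeded {MAX_LINEAGES} standing lineages at t={t:.3f}"
            )
    return FullTree(T=T, lineages=records)


# ---------------------------------------------------------------------------
# Reconstructed-tree extraction
# ---------------------------------------------------------------------------


def _build_induced_tree(
    records: list, reps: dict[int, str], T: float
) -> Optional[ReconstructedTree]:
    """Induced subtree of the lineage genealogy spanned by representatives.

    ``records`` provide ``id``, ``parent`` and ``birth``; the divergence time
    of two clades is the initiation (birth) time of the branch that separates
    them.  Children are merged onto their parent's path from youngest to
    oldest so that each merge point is the current child's birth time.
    """
    if not reps:
        return None
    children: dict[int, list[int]] = {}
    for rec in records:
        if rec.parent is not None:
            children.setdefault(rec.parent, []).append(rec.id)
    order = sorted(records, key=lambda r: r.birth, reverse=True)
    taxa = dendropy.TaxonNamespace()
    built: dict[int, dendropy.Node] = {}
    for rec in order:
        node: Optional[dendropy.Node] = None
        if rec.id in reps:
            node = dendropy.Node()
            node.taxon = taxa.new_taxon(label=reps[rec.id])
            node.time = T
        for child_id in sorted(children.get(rec.id, []), key=lambda i: records[i].birth, reverse=True):
            sub = built.pop(child_id, None)
            if sub is None:
                continue
            if node is None:
                node = sub
            else:
                joint = dendropy.Node()
                joint.time = records[child_id].birth
                joint.add_child(node)
                joint.add_child(sub)
                node = joint
        if node is not None:
            built[rec.id] = node
    root_id = next(rec.id for rec in records if rec.parent is None)
    root = built.get(root_id)
    if root is None:
        return None
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            nd.edge.length = nd.time - nd.parent_node.time
    # a single representative yields a one-tip tree whose stem spans [0, T]
    if root.is_leaf():
        return ReconstructedTree(tree, stem_length=T)
    return ReconstructedTree(tree, stem_length=root.time)


def extract_good_species_tree(
    full: FullTree,
    convention: str = "oldest",
    require_good_alive: bool = False,
) -> Optional[ReconstructedTree]:
    """Reconstructed ultrametric tree of extant good species.

    Each extant species becomes one tip, represented by its oldest (default)
    or youngest member lineage alive at the present; divergence times are the
    speciation-initiation times separating the representative lineages in the
    full genealogy.  Tip labels ``s<k>`` follow the order of species founding.
    Returns ``None`` when no species survives.
    """
    if convention not in ("oldest", "youngest"):
        raise ValueError(f"convention must be 'oldest' or 'youngest', got {convention!r}")
    species = full.extant_species(require_good_alive=require_good_alive)
    if not species:
        return None
    pick = min if convention == "oldest" else max
    reps = {
        pick(members, key=lambda rec: (rec.birth, rec.id)).id: f"s{label}"
        for label, members in species.items()
    }
    return _build_induced_tree(full.lineages, reps, full.T)


def count_extant_species(full: FullTree, require_good_alive: bool = False) -> int:
    return len(full.extant_species(require_good_alive=require_good_alive))


# ---------------------------------------------------------------------------
# Birth-death simulation (constant or piecewise-constant rates)
# ---------------------------------------------------------------------------


@dataclass
class _BDLineage:
    id: int
    parent: Optional[int]
    birth: float
    death: Optional[float] = None


def _simulate_bd_once(rates: PiecewiseConstantRates, T: float, rng) -> list[_BDLineage]:
    # one Exp(1) hazard draw per event, consumed across interval boundaries,
    # so identical rate functions yield identical trees for the same seed
    # regardless of how the intervals are cut
    lineages = [_BDLineage(id=0, parent=None, birth=0.0)]
    alive = [0]
    t = 0.0
    i = 0
    n_int = len(rates.lam)
    while alive and t < T:
        e = rng.exponential(1.0)
        while True:
            lam, mu = rates.lam[i], rates.mu[i]
            total = len(alive) * (lam + mu)
            boundary = min(rates.edges[i + 1], T)
            avail = (boundary - t) * total
            if total > 0.0 and e <= avail:
                t += e / total
                break
            e -= avail
            t = boundary
            if t >= T or i + 1 >= n_int:
                t = T
                break
            i += 1
        if t >= T:
            break
        pos = rng.integers(len(alive))
        if rng.uniform() < lam / (lam + mu):
            lineages.append(_BDLineage(id=len(lineages), parent=alive[pos], birth=t))
            alive.append(len(lineages) - 1)
        else:
            lineages[alive[pos]].death = t
            alive[pos] = alive[-1]
            alive.pop()
        if len(alive) > MAX_LINEAGES:
            raise SimulationExplosion(
                f"replicate exceeded {MAX_LINEAGES} standing lineages at t={t:.3f}"
            )
    return lineages


def simulate_bd(
    rates: PiecewiseConstantRates,
    config: SimulationConfig,
    rng=None,
) -> tuple[Optional[ReconstructedTree], int]:
    """Simulate a reconstructed BD tree under piecewise-constant rates.

    Starts from a single stem lineage at time 0 and retries (up to
    ``config.max_attempts``) until at least ``config.condition_on_survivors``
    lineages survive to the present.  Returns ``(tree, attempts)``; the tree
    is ``None`` when conditioning fails in every attempt.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    T = config.T
    for attempt in range(1, config.max_attempts + 1):
        lineages = _simulate_bd_once(rates, T, rng)
        survivors = [ln for ln in lineages if ln.death is None]
        if len(survivors) < max(config.condition_on_survivors, 1):
            continue
        reps = {ln.id: f"s{j + 1}" for j, ln in enumerate(survivors)}
        tree = _build_induced_tree(lineages, reps, T)
        return tree, attempt
    return None, config.max_attempts


def simulate_pbd_tree(
    params: PBDParams, config: SimulationConfig, rng=None
) -> tuple[Optional[ReconstructedTree], int]:
    """PBD replicate with survival conditioning on extant good species."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    for attempt in range(1, config.max_attempts + 1):
        full = simulate_pbd(params, config, rng=rng)
        if count_extant_species(full, config.require_good_alive) < max(
            config.condition_on_survivors, 1
        ):
            continue
        tree = extract_good_species_tree(
            full, convention=config.species_convention,
            require_good_alive=config.require_good_alive,
        )
        return tree, attempt
    return None, config.max_attempts


# ---------------------------------------------------------------------------
# Replicate batches and the three-model comparison
# ---------------------------------------------------------------------------


@dataclass
class ReplicateBatch:
    """A batch of reconstructed-tree replicates from one model.

    Invalid replicates (conditioning never satisfied within the attempt
    budget) are stored as ``None`` with the exhausted attempt count.
    """

    model: str
    trees: list[Optional[ReconstructedTree]] = field(default_factory=list)
    seeds: list[int] = field(default_factory=list)
    attempts: list[int] = field(default_factory=list)

    @property
    def n_valid(self) -> int:
        return sum(1 for t in self.trees if t is not None)

    def valid_trees(self) -> list[ReconstructedTree]:
        return [t for t in self.trees if t is not None]

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "replicate": np.arange(len(self.trees)),
                "seed": self.seeds,
                "attempts": self.attempts,
                "n_tips": [t.n_tips if t is not None else 0 for t in self.trees],
                "valid": [t is not None for t in self.trees],
            }
        )


def _replicate_seeds(root_seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(root_seed).generate_state(max(n, 1))[:n]


def simulate_pbd_batch(
    params: PBDParams, config: SimulationConfig, n_reps: int
) -> ReplicateBatch:
    seeds = _replicate_seeds(config.seed, n_reps)
    batch = ReplicateBatch(model="PBD")
    for s in seeds:
        tree, attempts = simulate_pbd_tree(params, config, rng=np.random.default_rng(int(s)))
        batch.trees.append(tree)
        batch.seeds.append(int(s))
        batch.attempts.append(attempts)
    return batch


def simulate_bd_batch(
    rates: PiecewiseConstantRates,
    config: SimulationConfig,
    n_reps: int,
    model: str = "BD",
) -> ReplicateBatch:
    seeds = _replicate_seeds(config.seed, n_reps)
    batch = ReplicateBatch(model=model)
    for s in seeds:
        tree, attempts = simulate_bd(rates, config, rng=np.random.default_rng(int(s)))
        batch.trees.append(tree)
        batch.seeds.append(int(s))
        batch.attempts.append(attempts)
    return batch


def run_comparison_experiment(
    params: PBDParams, config: SimulationConfig, n_reps: int = 200
) -> dict[str, ReplicateBatch]:
    """Simulate matched batches under PBD, the equivalent time-varying BD
    (``varBD``, piecewise-constant over ``config.n_grid`` intervals) and the
    equivalent constant-rate BD."""
    traj = equivalent_rate_trajectory(params, config.T, max(config.n_grid, 2))
    var_rates = discretize_trajectory(traj, config.n_grid)
    const = equivalent_constant_rates(params)
    const_rates = PiecewiseConstantRates.constant(const.lambda_tilde, const.mu_tilde, config.T)
    return {
        "PBD": simulate_pbd_batch(params, config, n_reps),
        "varBD": simulate_bd_batch(var_rates, config, n_reps, model="varBD"),
        "BD": simulate_bd_batch(const_rates, config, n_reps, model="BD"),
    }
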