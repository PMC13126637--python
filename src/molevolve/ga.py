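"""Docking-score-guided genetic optimization of molecule populations.

The trained policies act as mutational operators: each generation, every
elite-pool member is processed by a policy variant drawn uniformly from the
M = 1, 2, 3 checkpoints, which generates 10 offspring by independent
rollouts of at most M transformation steps.  Offspring are scored by a
user-supplied docking-score callable (kcal/mol, lower better), ranked by
ligand efficiency LE = DS / sqrt(heavy atoms), and re-selected into an
elite pool of up to 20 members under a Tanimoto diversity filter: scanning
from the best candidate, a molecule joins the elite only if its maximum
similarity to the current elite is below ``sim_cut``.

Two archives persist: the current elite pool, and a global archive of every
unique molecule ever scored (with DS, LE, QED, SA, logP, MW and chiral
count).  Termination uses a four-criterion rule — sustained stagnation of
the best fitness, of the mean fitness, a collapsed per-generation
population, and a minimum generation count — requiring at least three
criteria simultaneously.

Dual-target campaigns rank by the harmonic mean F = 2*LE1*LE2/(LE1+LE2) of
the per-target ligand efficiencies, which rewards balanced binders; the
harmonic mean is only order-consistent for same-sign values, so any
candidate whose LEs are not both negative receives a worst-case sentinel
fitness.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .policy import PolicyNetwork
from .properties import (
    PropertyVector,
    compute_properties,
    fingerprint,
    ligand_efficiency,
    tanimoto,
)
from .records import MoleculeRecord, mol_from_smiles
from .reinforce import policy_rollout

log = logging.getLogger(__name__)

WORST_FITNESS = float("inf")


@dataclass
class GAConfig:
    elite_size: int = 20                   # N
    sim_cut: float = 0.4
    offspring_per_elite: int = 10
    mode: str = "single_target"            # or "dual_target"
    scaffold_constraint: Optional[str] = None
    stagnation_window: int = 25
    mean_improvement_eps: float = 0.1      # kcal/mol
    population_floor: int = 100
    min_generations: int = 100
    criteria_required: int = 3
    max_generations: int = 1000
    rng_seed: int = 0

    def __post_init__(self):
        if not 0 < self.sim_cut <= 1:
            raise ValueError("sim_cut must lie in (0, 1]")
        if self.mode not in ("single_target", "dual_target"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class ScoreRecord:
    ds: tuple                  # one DS per target
    le: tuple                  # one LE per target
    fitness: float
    props: PropertyVector


@dataclass
class EliteMember:
    record: MoleculeRecord
    score: ScoreRecord
    fp: object  # cached Morgan fingerprint


@dataclass
class TraceRow:
    generation: int
    best_fitness: float
    mean_fitness: float
    population_size: int
    new_global_best: bool


def fitness(le_values: Sequence[float], mode: str) -> float:
    """Campaign fitness from per-target ligand efficiencies (lower=better)."""
    if mode == "single_target":
        if len(le_values) != 1:
            raise ValueError("single_target mode expects one score")
        return float(le_values[0])
    if len(le_values) != 2:
        raise ValueError("dual_target mode expects two scores")
    le1, le2 = le_values
    if le1 >= 0 or le2 >= 0:
        return WORST_FITNESS
    return 2.0 * le1 * le2 / (le1 + le2)


def score_molecule(record: MoleculeRecord, scorers, mode: str) -> ScoreRecord:
    ds = tuple(float(s(record.smiles)) for s in scorers)
    le = tuple(ligand_efficiency(d, record.heavy_atom_count) for d in ds)
    return ScoreRecord(ds=ds, le=le, fitness=fitness(le, mode),
                       props=compute_properties(record))


def select_elite(candidates: Sequence[EliteMember], elite_size: int,
                 sim_cut: float) -> list[EliteMember]:
    """Greedy diversity-filtered selection from fitness-ranked candidates.

    ``candidates`` must already be sorted by fitness ascending (best
    first); the global best is always accepted, so it ends up as elite[0].
    """
    elite: list[EliteMember] = []
    for cand in candidates:
        if len(elite) >= elite_size:
            break
        if all(tanimoto(cand.fp, e.fp) < sim_cut for e in elite):
            elite.append(cand)
    return elite


def _satisfies_scaffold(record: MoleculeRecord, pattern: Chem.Mol) -> bool:
    return record.to_mol().HasSubstructMatch(pattern)


class Campaign:
    """State of one optimization run: elite pool, archive, trace."""

    def __init__(self, config: GAConfig, scorers, policy_variants):
        if not scorers:
            raise ValueError("at least one scorer is required")
        n_expected = 2 if config.mode == "dual_target" else 1
        if len(scorers) != n_expected:
            raise ValueError(
                f"{config.mode} mode requires {n_expected} scorer(s)")
        self.config = config
        self.scorers = list(scorers)
        self.policy_variants = list(policy_variants)  # [(M, PolicyNetwork)]
        self.archive: dict[str, EliteMember] = {}
        self.elite: list[EliteMember] = []
        self.trace: list[TraceRow] = []
        self.rng = np.random.default_rng(config.rng_seed)
        self._pattern = None
        if config.scaffold_constraint:
            self._pattern = mol_from_smiles(config.scaffold_constraint)
        self._best = WORST_FITNESS
        self._best_mean = WORST_FITNESS
        self._max_population = 0

    # -- scoring -------------------------------------------------------------

    def _score(self, record: MoleculeRecord) -> Optional[EliteMember]:
        cached = self.archive.get(record.smiles)
        if cached is not None:
            return cached
        try:
            score = score_molecule(record, self.scorers, self.config.mode)
        except Exception as exc:
            log.warning("scorer failed for %s: %s", record.smiles, exc)
            return None
        member = EliteMember(record=record, score=score,
                             fp=fingerprint(record))
        self.archive[record.smiles] = member
        return member

    def initialize(self, seeds: Sequence[MoleculeRecord]) -> None:
        if not seeds:
            raise ValueError("at least one seed molecule is required")
        if self._pattern is not None:
            for s in seeds:
                if not _satisfies_scaffold(s, self._pattern):
                    raise ValueError(
                        f"seed {s.smiles} violates the scaffold constraint")
        members = [m for m in (self._score(s) for s in seeds) if m is not None]
        if not members:
            raise RuntimeError("no seed could be scored")
        members.sort(key=lambda m: m.score.fitness)
        self.elite = select_elite(members, self.config.elite_size,
                                  self.config.sim_cut)
        self._best = self.elite[0].score.fitness

    # -- one generation -------------------------------------------------------

    def generation_step(self, library=None) -> TraceRow:
        cfg = self.config
        new_unique: dict[str, MoleculeRecord] = {}
        for member in self.elite:
            m_steps, policy = self.policy_variants[
                int(self.rng.integers(len(self.policy_variants)))]
            for _ in range(cfg.offspring_per_elite):
                child, _steps = policy_rollout(
                    policy, member.record, m_steps, self.rng, library,
                    record_steps=False)
                if child.smiles == member.record.smiles:
                    continue
                if self._pattern is not None and not _satisfies_scaffold(
                        child, self._pattern):
                    continue
                if child.smiles not in self.archive:
                    new_unique[child.smiles] = child
        scored = [m for m in (self._score(r) for r in new_unique.values())
                  if m is not None]
        population_size = len(scored)
        self._max_population = max(self._max_population, population_size)

        pool = list({m.record.smiles: m for m in self.elite + scored}.values())
        pool.sort(key=lambda m: m.score.fitness)
        self.elite = select_elite(pool, cfg.elite_size, cfg.sim_cut)

        best = self.elite[0].score.fitness
        finite = [m.score.fitness for m in scored
                  if m.score.fitness < WORST_FITNESS]
        mean_fit = float(np.mean(finite)) if finite else best
        new_best = best < self._best
        self._best = min(self._best, best)
        row = TraceRow(generation=len(self.trace) + 1, best_fitness=self._best,
                       mean_fitness=mean_fit, population_size=population_size,
                       new_global_best=new_best)
        self.trace.append(row)
        return row

    # -- persistence ----------------------------------------------------------

    def archive_frame(self) -> pd.DataFrame:
        rows = []
        for smi, m in self.archive.items():
            row = {"smiles": smi, "DS": m.score.ds[0], "LE": m.score.le[0],
                   "QED": m.score.props.qed, "SA": m.score.props.sa_raw,
                   "logP": m.score.props.logp, "MW": m.score.props.mw,
                   "n_chiral": m.score.props.n_chiral}
            if self.config.mode == "dual_target":
                row["DS2"] = m.score.ds[1]
                row["LE2"] = m.score.le[1]
                row["F"] = m.score.fitness
            rows.append(row)
        return pd.DataFrame(rows)

    def trace_frame(self) -> pd.DataFrame:
        return pd.DataFrame([t.__dict__ for t in self.trace])


def check_convergence(trace: Sequence[TraceRow], config: GAConfig,
                      max_population: Optional[int] = None):
    """Evaluate the four termination criteria on a trace.

    1: no new global best for ``stagnation_window`` consecutive generations;
    2: mean fitness has not improved by ``mean_improvement_eps`` for that
    window; 3: population below ``population_floor`` for the whole window
    (after having reached the floor at least once); 4: at least
    ``min_generations`` generations.  Converged when at least
    ``criteria_required`` hold simultaneously.
    """
    if not trace:
        raise ValueError("empty trace")
    w = config.stagnation_window
    satisfied = set()
    recent = trace[-w:]
    if len(recent) == w and not any(t.new_global_best for t in recent):
        satisfied.add(1)
    # mean-fitness improvement relative to the best mean seen before each gen
    best_mean = math.inf
    since_improve = 0
    for t in trace:
        if t.mean_fitness <= best_mean - config.mean_improvement_eps:
            since_improve = 0
        else:
            since_improve += 1
        best_mean = min(best_mean, t.mean_fitness)
    if since_improve >= w:
        satisfied.add(2)
    if max_population is None:
        max_population = max(t.population_size for t in trace)
    if (max_population >= config.population_floor and len(recent) == w
            and all(t.population_size < config.population_floor
                    for t in recent)):
        satisfied.add(3)
    if trace[-1].generation >= config.min_generations:
        satisfied.add(4)
    return len(satisfied) >= config.criteria_required, satisfied


def run_campaign(seeds: Sequence[MoleculeRecord], config: GAConfig, scorers,
                 policy_variants, library=None,
                 out_dir: Optional[str] = None) -> Campaign:
    """Run generations until convergence or the hard generation cap.

    ``policy_variants`` is a list of (M, PolicyNetwork) pairs; one variant
    is drawn per elite member per generation.  Writes ``archive.csv`` and
    ``trace.csv`` under ``out_dir`` when given.
    """
    campaign = Campaign(config, scorers, policy_variants)
    campaign.initialize(seeds)
    for _ in range(config.max_generations):
        campaign.generation_step(library)
        converged, which = check_convergence(
            campaign.trace, config, campaign._max_population)
        if converged:
            log.info("converged at generation %d (criteria %s)",
                     len(campaign.trace), sorted(which))
            break
    else:
        log.warning("hit hard generation cap (%d) without convergence",
                    config.max_generations)
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        campaign.archive_frame().to_csv(
            os.path.join(out_dir, "archive.csv"), index=False)
        campaign.trace_frame().to_csv(
            os.path.join(out_dir, "trace.csv"), index=False)
    return campaign
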