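"""Library-level evaluation metrics for generated molecule sets.

Covers the generation-quality panel (unicity, similarity to sources, SA,
QED), diversity measures (internal diversity, maximum similarity to known
actives T_MAX, Bemis-Murcko scaffold diversity S_d), distribution-learning
metrics in the GuacaMol/MOSES tradition (novelty, scaffold novelty, BRICS
fragment and scaffold frequency cosine similarity, KL divergence over nine
physicochemical descriptors), and activity-cliff detection on scored
archives.

KL divergence is estimated from shared-support histograms (Scott-rule bins
on the parent set for continuous descriptors; smoothed empirical mass
functions for counts) with Laplace smoothing.  Both the raw average KL and
the benchmark-style exponentiated aggregate exp(-mean KL) are reported.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors
from rdkit.Chem.Scaffolds import MurckoScaffold

from .fragments import brics_fragments
from .properties import fingerprint, qed_score, sa_score, tanimoto
from .records import canonical_smiles, mol_from_smiles

KL_DESCRIPTORS = {
    "BertzCT": ("continuous", Descriptors.BertzCT),
    "MolLogP": ("continuous", Descriptors.MolLogP),
    "MolWt": ("continuous", Descriptors.MolWt),
    "TPSA": ("continuous", Descriptors.TPSA),
    "NumHAcceptors": ("count", Descriptors.NumHAcceptors),
    "NumHDonors": ("count", Descriptors.NumHDonors),
    "NumRotatableBonds": ("count", Descriptors.NumRotatableBonds),
    "NumAliphaticRings": ("count", Descriptors.NumAliphaticRings),
    "NumAromaticRings": ("count", Descriptors.NumAromaticRings),
}


@dataclass
class MetricsReport:
    unicity: float = math.nan                  # percent
    mean_sim: float = math.nan
    sd_sim: float = math.nan
    mean_sa: float = math.nan
    sd_sa: float = math.nan
    mean_qed: float = math.nan
    sd_qed: float = math.nan
    internal_diversity: float = math.nan
    t_max_mean: float = math.nan
    t_max_sd: float = math.nan
    scaffold_diversity: float = math.nan
    novelty: float = math.nan
    scaffold_novelty: float = math.nan
    fragment_similarity: float = math.nan
    scaffold_similarity: float = math.nan
    kl_divergence: float = math.nan
    kl_divergence_score: float = math.nan      # exp(-mean KL), benchmark style

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if not math.isnan(v)}


def _scaffold(smiles: str) -> str:
    return MurckoScaffold.MurckoScaffoldSmiles(smiles=smiles)


def library_metrics(generated: Sequence[str],
                    sources: Optional[dict] = None,
                    references: Optional[Sequence[str]] = None
                    ) -> MetricsReport:
    """Generation-quality and diversity panel for a molecule library.

    ``generated`` may contain duplicates (unicity counts them); ``sources``
    maps generated SMILES to their source SMILES for the similarity column;
    ``references`` are known actives for T_MAX.  T_MAX is omitted (NaN), not
    zeroed, when no references are supplied.
    """
    generated = list(generated)
    if not generated:
        raise ValueError("empty generated set")
    canon = [canonical_smiles(s) for s in generated]
    unique = sorted(set(canon))
    report = MetricsReport()
    report.unicity = 100.0 * len(unique) / len(canon)

    sas = [sa_score(s) for s in unique]
    qeds = [qed_score(s) for s in unique]
    report.mean_sa, report.sd_sa = float(np.mean(sas)), float(np.std(sas))
    report.mean_qed, report.sd_qed = float(np.mean(qeds)), float(np.std(qeds))

    if sources:
        sims = [tanimoto(fingerprint(g), fingerprint(src))
                for g, src in ((g, sources.get(g)) for g in generated)
                if src is not None]
        if sims:
            report.mean_sim = float(np.mean(sims))
            report.sd_sim = float(np.std(sims))

    fps = [fingerprint(s) for s in unique]
    if len(fps) > 1:
        pair_sims = [tanimoto(a, b) for a, b in itertools.combinations(fps, 2)]
        report.internal_diversity = 1.0 - float(np.mean(pair_sims))

    if references:
        ref_fps = [fingerprint(s) for s in references]
        t_max = [max(tanimoto(f, rf) for rf in ref_fps) for f in fps]
        report.t_max_mean = float(np.mean(t_max))
        report.t_max_sd = float(np.std(t_max))

    scaffolds = {_scaffold(s) for s in unique}
    report.scaffold_diversity = len(scaffolds) / len(unique)
    return report


def _frequency_cosine(items_a: Sequence[str], items_b: Sequence[str]) -> float:
    vocab = sorted(set(items_a) | set(items_b))
    index = {v: i for i, v in enumerate(vocab)}
    va = np.zeros(len(vocab))
    vb = np.zeros(len(vocab))
    for x in items_a:
        va[index[x]] += 1
    for x in items_b:
        vb[index[x]] += 1
    denom = np.linalg.norm(va) * np.linalg.norm(vb)
    return float(va @ vb / denom) if denom else 0.0


def _kl(p: np.ndarray, q: np.ndarray) -> float:
    mask = p > 0
    return float((p[mask] * np.log(p[mask] / q[mask])).sum())


def _descriptor_kl(gen_vals: np.ndarray, par_vals: np.ndarray,
                   kind: str) -> float:
    """KL(parent || generated) over one descriptor's distribution."""
    if kind == "count":
        hi = int(max(gen_vals.max(), par_vals.max()))
        edges = np.arange(-0.5, hi + 1.5)
    else:
        # Scott-rule bin width on the parent sample, shared support
        sd = par_vals.std()
        n = len(par_vals)
        width = 3.49 * sd / n ** (1 / 3) if sd > 0 else 1.0
        lo = min(gen_vals.min(), par_vals.min())
        hi = max(gen_vals.max(), par_vals.max())
        n_bins = max(1, int(math.ceil((hi - lo) / width))) if hi > lo else 1
        n_bins = min(n_bins, 200)
        edges = np.linspace(lo, hi + 1e-9, n_bins + 1)
    hp, _ = np.histogram(par_vals, bins=edges)
    hg, _ = np.histogram(gen_vals, bins=edges)
    # Laplace smoothing keeps the estimate finite on disjoint supports
    p = (hp + 1.0) / (hp.sum() + len(hp))
    q = (hg + 1.0) / (hg.sum() + len(hg))
    return _kl(p, q)


def distribution_metrics(generated: Sequence[str],
                         parents: Sequence[str]) -> MetricsReport:
    """Distribution-learning metrics of a generated set vs its parent set.

    Novelty fractions use canonical-SMILES membership; fragment/scaffold
    similarities are cosines between frequency vectors over the union
    vocabulary of BRICS fragments / Bemis-Murcko scaffolds.
    """
    gen = sorted({canonical_smiles(s) for s in generated})
    par = sorted({canonical_smiles(s) for s in parents})
    if len(gen) < 2 or len(par) < 2:
        raise ValueError("need at least two distinct molecules per set")
    report = MetricsReport()
    par_set = set(par)
    report.novelty = sum(1 for s in gen if s not in par_set) / len(gen)

    gen_scaf = [_scaffold(s) for s in gen]
    par_scaf = [_scaffold(s) for s in par]
    par_scaf_set = set(par_scaf)
    gen_scaf_unique = set(gen_scaf)
    report.scaffold_novelty = (
        sum(1 for s in gen_scaf_unique if s not in par_scaf_set)
        / len(gen_scaf_unique))

    gen_frags = [f for s in gen for f in brics_fragments(mol_from_smiles(s))]
    par_frags = [f for s in par for f in brics_fragments(mol_from_smiles(s))]
    report.fragment_similarity = _frequency_cosine(gen_frags, par_frags)
    report.scaffold_similarity = _frequency_cosine(gen_scaf, par_scaf)

    kls = []
    gen_mols = [mol_from_smiles(s) for s in gen]
    par_mols = [mol_from_smiles(s) for s in par]
    for name, (kind, fn) in KL_DESCRIPTORS.items():
        gvals = np.array([fn(m) for m in gen_mols], dtype=float)
        pvals = np.array([fn(m) for m in par_mols], dtype=float)
        kls.append(_descriptor_kl(gvals, pvals, kind))
    report.kl_divergence = float(np.mean(kls))
    report.kl_divergence_score = float(math.exp(-report.kl_divergence))
    return report


@dataclass(frozen=True)
class ActivityCliffPair:
    smiles_a: str
    smiles_b: str
    similarity: float
    delta_ds: float
    attributed_actions: tuple


def find_activity_cliffs(archive, sim_threshold: float = 0.8,
                         ds_threshold: float = 2.0) -> list[ActivityCliffPair]:
    """All unordered molecule pairs with high similarity but a large docking
    score gap.

    ``archive`` maps canonical SMILES to objects with a ``score.ds`` tuple
    and a ``record.lineage``; the attributed actions are the symmetric
    difference of the two lineages' action sequences.
    """
    entries = sorted(archive.items())
    fps = {smi: fingerprint(smi) for smi, _ in entries}
    cliffs = []
    for (sa_, ma), (sb, mb) in itertools.combinations(entries, 2):
        sim = tanimoto(fps[sa_], fps[sb])
        if sim < sim_threshold:
            continue
        delta = abs(ma.score.ds[0] - mb.score.ds[0])
        if delta < ds_threshold:
            continue
        la = [step[0] for step in ma.record.lineage]
        lb = [step[0] for step in mb.record.lineage]
        attributed = tuple(sorted(set(la) ^ set(lb)))
        cliffs.append(ActivityCliffPair(sa_, sb, sim, delta, attributed))
    return cliffs
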