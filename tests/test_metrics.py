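"""Library, distribution-learning and activity-cliff metrics."""

import math
from types import SimpleNamespace

import numpy as np
import pytest
from rdkit import Chem

from molevolve import (
    MoleculeRecord,
    distribution_metrics,
    find_activity_cliffs,
    library_metrics,
)
from molevolve.fragments import brics_fragments
from molevolve.properties import fingerprint, tanimoto


class TestLibraryMetrics:
    def test_unicity_counts_duplicates(self):
        rep = library_metrics(["CCO", "OCC", "c1ccccc1"])
        assert rep.unicity == pytest.approx(100 * 2 / 3)
        rep_all = library_metrics(["CCO", "c1ccccc1", "CC(N)=O"])
        assert rep_all.unicity == 100.0

    def test_scaffold_diversity_hand_count(self):
        # four molecules on two Bemis-Murcko scaffolds (benzene, cyclohexane)
        mols = ["Cc1ccccc1", "CCc1ccccc1", "CC1CCCCC1", "CCC1CCCCC1"]
        rep = library_metrics(mols)
        assert rep.scaffold_diversity == pytest.approx(0.5)

    def test_tmax_and_id_on_disjoint_sets(self):
        gen = ["CCCCCCCC", "c1ccccc1"]
        refs = ["O=S(=O)(N)c1ccc(Cl)cc1"]
        rep = library_metrics(gen, references=refs)
        assert rep.internal_diversity == pytest.approx(
            1.0 - tanimoto(fingerprint(gen[0]), fingerprint(gen[1])))
        hand_tmax = np.mean([
            max(tanimoto(fingerprint(g), fingerprint(r)) for r in refs)
            for g in sorted({Chem.MolToSmiles(Chem.MolFromSmiles(s))
                             for s in gen})])
        assert rep.t_max_mean == pytest.approx(hand_tmax)

    def test_tmax_omitted_without_references(self):
        rep = library_metrics(["CCO", "CCN"])
        assert math.isnan(rep.t_max_mean)

    def test_permutation_invariant(self, corpus100):
        a = library_metrics(corpus100[:12])
        b = library_metrics(list(reversed(corpus100[:12])))
        assert a.unicity == b.unicity
        assert a.internal_diversity == pytest.approx(b.internal_diversity)
        assert a.scaffold_diversity == b.scaffold_diversity

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            library_metrics([])


class TestDistributionMetrics:
    def test_identity_case(self, corpus100):
        subset = corpus100[:15]
        rep = distribution_metrics(subset, subset)
        assert rep.novelty == 0.0
        assert rep.scaffold_novelty == 0.0
        assert rep.fragment_similarity == pytest.approx(1.0)
        assert rep.scaffold_similarity == pytest.approx(1.0)
        assert rep.kl_divergence == pytest.approx(0.0, abs=1e-12)
        assert rep.kl_divergence_score == pytest.approx(1.0)

    def test_disjoint_sets_fully_novel(self):
        gen = ["CCCCCCCCCC", "CCCCCCCCC"]
        par = ["c1ccc2ccccc2c1", "Clc1ccc2ccccc2c1"]
        rep = distribution_metrics(gen, par)
        assert rep.novelty == 1.0
        assert rep.scaffold_novelty == 1.0

    def test_fragment_cosine_matches_hand_computation(self):
        gen = ["CCCCC(=O)OCc1ccccc1", "CCCC(=O)NCc1ccccc1"]
        par = ["CCCCC(=O)OCc1ccccc1", "CCCCCCCC(=O)OC1CCCCC1"]
        rep = distribution_metrics(gen, par)
        gf, pf = {}, {}
        for s, d in [(gen, gf), (par, pf)]:
            for smi in sorted({Chem.MolToSmiles(Chem.MolFromSmiles(x))
                               for x in s}):
                for f in brics_fragments(Chem.MolFromSmiles(smi)):
                    d[f] = d.get(f, 0) + 1
        vocab = sorted(set(gf) | set(pf))
        va = np.array([gf.get(v, 0) for v in vocab], float)
        vb = np.array([pf.get(v, 0) for v in vocab], float)
        cos = va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb))
        assert rep.fragment_similarity == pytest.approx(cos)

    def test_degenerate_sets_rejected(self):
        with pytest.raises(ValueError):
            distribution_metrics(["CCO"], ["CCO", "CCN"])

    def test_kl_bounded_below_by_zero(self, corpus100):
        rep = distribution_metrics(corpus100[:20], corpus100[20:60])
        assert rep.kl_divergence >= 0.0
        assert 0.0 < rep.kl_divergence_score <= 1.0


def fake_archive(entries):
    """smiles -> object with .score.ds and .record.lineage."""
    out = {}
    for smi, ds, lineage in entries:
        rec = MoleculeRecord.from_smiles(smi)
        out[rec.smiles] = SimpleNamespace(
            score=SimpleNamespace(ds=(ds,)),
            record=SimpleNamespace(lineage=lineage, smiles=rec.smiles))
    return out


class TestActivityCliffs:
    def test_identical_structure_pair_detected(self):
        # same fingerprint (homologous long chains), DS gap 3 kcal/mol
        archive = fake_archive([
            ("CCCCCCCCCCCC", -9.0, (("HALOGENATE", ()),)),
            ("CCCCCCCCCCCCC", -6.0, (("NITRATE", ()),)),
        ])
        pairs = find_activity_cliffs(archive)
        assert len(pairs) == 1
        assert pairs[0].similarity >= 0.8
        assert pairs[0].delta_ds == pytest.approx(3.0)
        assert pairs[0].attributed_actions == ("HALOGENATE", "NITRATE")

    def test_dissimilar_molecules_ignored(self):
        archive = fake_archive([
            ("c1ccccc1", -9.0, ()),
            ("CCCCCCCC", -5.0, ()),
        ])
        assert find_activity_cliffs(archive) == []

    def test_matches_bruteforce_scan(self):
        entries = [
            ("CCCCCCCCCC", -9.0, ()),
            ("CCCCCCCCCCC", -6.5, ()),
            ("CCCCCCCCCCCC", -8.9, ()),
            ("c1ccc(Cl)cc1", -4.0, ()),
            ("c1ccc(Br)cc1", -7.0, ()),
        ]
        archive = fake_archive(entries)
        got = {(p.smiles_a, p.smiles_b) for p in find_activity_cliffs(archive)}
        import itertools

        expected = set()
        for (sa, ma), (sb, mb) in itertools.combinations(
                sorted(archive.items()), 2):
            sim = tanimoto(fingerprint(sa), fingerprint(sb))
            if sim >= 0.8 and abs(ma.score.ds[0] - mb.score.ds[0]) >= 2.0:
                expected.add((sa, sb))
        assert got == expected
        assert expected  # the crafted set does contain cliffs
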