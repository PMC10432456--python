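"""The synthetic oracle generator: marginals, coupling, determinism."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from maskstack.core import ALPHABET, PROB_COLUMNS, ValidationError
from maskstack.evaluation import add_call_columns, per_protein_accuracy
from maskstack.synthetic import (
    BURIAL_THRESHOLD,
    OracleProfile,
    ProteinSimSpec,
    expected_marginal_accuracy,
    generate_benchmark,
    generate_oracle_predictions,
    generate_proteins,
    paper_like_profiles,
    uniform_profile,
)


def _flat_profile(model_id: str, family: str, p: float) -> OracleProfile:
    """Uniform-accuracy profile with all coupling and noise switched off."""
    return uniform_profile(
        model_id,
        family,
        p,
        site_coupling=0.0,
        shared_coupling=0.0,
        difficulty_slope=0.0,
        protein_shared_sd=0.0,
        protein_common_sd=0.0,
        protein_own_sd=0.0,
    )


class TestGenerateProteins:
    def test_degenerate_composition_gives_poly_a(self):
        comp = np.zeros(20)
        comp[0] = 1.0
        spec = ProteinSimSpec(n_proteins=3, length_range=(10, 10), composition=comp)
        for rec in generate_proteins(spec, seed=0):
            assert rec.sequence == "A" * 10

    def test_same_seed_reproduces_identical_proteins(self):
        spec = ProteinSimSpec(n_proteins=4, length_range=(30, 80))
        a = generate_proteins(spec, seed=3)
        b = generate_proteins(spec, seed=3)
        assert [(r.identifier, r.sequence) for r in a] == [
            (r.identifier, r.sequence) for r in b
        ]
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.rsa, rb.rsa)

    def test_uniform_composition_frequencies_within_binomial_bounds(self):
        comp = np.full(20, 0.05)
        spec = ProteinSimSpec(n_proteins=200, length_range=(100, 100), composition=comp)
        records = generate_proteins(spec, seed=11)
        seq = "".join(r.sequence for r in records)
        n = len(seq)
        se = np.sqrt(0.05 * 0.95 / n)
        for aa in ALPHABET:
            freq = seq.count(aa) / n
            assert abs(freq - 0.05) < 3 * se

    def test_burial_model_respects_threshold(self):
        spec = ProteinSimSpec(n_proteins=20, length_range=(100, 100), p_buried=0.5)
        records = generate_proteins(spec, seed=5)
        rsa = np.concatenate([r.rsa for r in records])
        buried_frac = (rsa < BURIAL_THRESHOLD).mean()
        assert abs(buried_frac - 0.5) < 3 * np.sqrt(0.25 / len(rsa))

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_proteins": 0},
            {"n_proteins": 2, "length_range": (50, 20)},
            {"n_proteins": 2, "length_range": (10, 2000)},
        ],
    )
    def test_degenerate_specs_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            ProteinSimSpec(**kwargs)


class TestOraclePredictions:
    def _protein(self, n=400, seed=2):
        spec = ProteinSimSpec(n_proteins=1, length_range=(n, n))
        return generate_proteins(spec, seed=seed)[0]

    def test_perfect_oracle_always_names_the_wildtype(self):
        prot = self._protein()
        preds = add_call_columns(
            generate_oracle_predictions(prot, _flat_profile("m", "structure", 1.0), seed=0)
        )
        assert preds["correct"].all()

    def test_hopeless_oracle_never_names_the_wildtype(self):
        prot = self._protein()
        preds = add_call_columns(
            generate_oracle_predictions(prot, _flat_profile("m", "structure", 0.0), seed=0)
        )
        assert not preds["correct"].any()

    def test_marginal_accuracy_matches_profile_at_10000_sites(self):
        spec = ProteinSimSpec(n_proteins=100, length_range=(100, 100))
        profile = _flat_profile("m", "sequence", 0.65)
        bench_profiles = [
            profile,
            _flat_profile("s1", "structure", 0.5),
            _flat_profile("s2", "structure", 0.5),
            _flat_profile("q2", "sequence", 0.5),
        ]
        bench = generate_benchmark(spec, bench_profiles, seed=21)
        scored = add_call_columns(bench.predictions_for("m"))
        n = len(scored)
        assert n == 10_000
        se = np.sqrt(0.65 * 0.35 / n)
        assert abs(scored["correct"].mean() - 0.65) < 3 * se

    def test_emitted_vectors_are_valid_distributions(self, fixture_benchmarks):
        train, _ = fixture_benchmarks
        probs = train.predictions[PROB_COLUMNS].to_numpy()
        assert (probs >= 0).all()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_regeneration_is_byte_identical(self, fixture_config):
        from maskstack.pipeline import simulate

        t1, e1 = simulate(fixture_config)
        t2, e2 = simulate(fixture_config)
        assert t1.predictions.to_csv() == t2.predictions.to_csv()
        assert e1.predictions.to_csv() == e2.predictions.to_csv()


class TestBenchmarkValidation:
    def test_wrong_profile_count_rejected(self):
        spec = ProteinSimSpec(n_proteins=2, length_range=(20, 20))
        profiles = paper_like_profiles()[:3]
        with pytest.raises(ValidationError, match="four"):
            generate_benchmark(spec, profiles, seed=0)

    def test_wrong_family_balance_rejected(self):
        spec = ProteinSimSpec(n_proteins=2, length_range=(20, 20))
        profiles = [_flat_profile(f"m{i}", "structure", 0.5) for i in range(4)]
        with pytest.raises(ValidationError, match="structure"):
            generate_benchmark(spec, profiles, seed=0)


@pytest.fixture(scope="module")
def coupled_benchmark():
    spec = ProteinSimSpec(n_proteins=150, length_range=(80, 200), id_prefix="CPL")
    return generate_benchmark(spec, paper_like_profiles(), seed=17)


class TestCouplingStructure:
    """The latent-difficulty machinery shapes cross-oracle correlation."""

    def test_within_family_correlation_exceeds_cross_family(self, coupled_benchmark):
        acc = per_protein_accuracy(add_call_columns(coupled_benchmark.predictions))
        r = acc.corr()
        within = [r.loc["struct_a", "struct_b"], r.loc["seq_a", "seq_b"]]
        cross = [
            r.loc[a, b]
            for a in ("struct_a", "struct_b")
            for b in ("seq_a", "seq_b")
        ]
        assert min(within) > max(cross)

    def test_zero_coupling_gives_near_zero_correlation(self):
        spec = ProteinSimSpec(n_proteins=150, length_range=(100, 150))
        profiles = [
            _flat_profile("s1", "structure", 0.6),
            _flat_profile("s2", "structure", 0.6),
            _flat_profile("q1", "sequence", 0.6),
            _flat_profile("q2", "sequence", 0.6),
        ]
        bench = generate_benchmark(spec, profiles, seed=13)
        acc = per_protein_accuracy(add_call_columns(bench.predictions))
        r = acc.corr()
        for a in acc.columns:
            for b in acc.columns:
                if a < b:
                    assert abs(r.loc[a, b]) < 0.25  # ~zero up to sampling noise

    def test_identical_profiles_agree_on_class_accuracy(self):
        from maskstack.evaluation import class_accuracy

        spec = ProteinSimSpec(n_proteins=60, length_range=(150, 150))
        profiles = [
            _flat_profile("s1", "structure", 0.6),
            _flat_profile("s2", "structure", 0.6),
            _flat_profile("q1", "sequence", 0.6),
            _flat_profile("q2", "sequence", 0.6),
        ]
        bench = generate_benchmark(spec, profiles, seed=29)
        scored = add_call_columns(bench.predictions)
        per_model = {
            m: class_accuracy(sub).set_index("aa_class")["accuracy"]
            for m, sub in scored.groupby("model_id")
        }
        frame = pd.DataFrame(per_model)
        # identical profiles: per-class accuracies agree within sampling error
        assert float((frame.max(axis=1) - frame.min(axis=1)).max()) < 0.08

    def test_complementary_class_burial_strengths(self, coupled_benchmark):
        """Structure-like oracles win on buried aliphatic sites; sequence-like
        on exposed polar sites."""
        bench = coupled_benchmark
        scored = add_call_columns(bench.predictions)
        site_info = pd.concat(
            [
                pd.DataFrame(
                    {
                        "protein_id": rec.identifier,
                        "site": np.arange(1, len(rec) + 1),
                        "rsa": rec.rsa,
                    }
                )
                for rec in bench.proteins
            ],
            ignore_index=True,
        )
        scored = scored.merge(site_info, on=["protein_id", "site"])
        scored["buried"] = scored["rsa"] < BURIAL_THRESHOLD

        def acc(model, mask):
            sub = scored[(scored["model_id"] == model) & mask]
            return sub["correct"].mean()

        buried_aliphatic = scored["buried"] & scored["wildtype"].isin(list("AILMV"))
        exposed_polar = ~scored["buried"] & scored["wildtype"].isin(list("CNQST"))
        for s in ("struct_a", "struct_b"):
            for q in ("seq_a", "seq_b"):
                assert acc(s, buried_aliphatic) > acc(q, buried_aliphatic)
                assert acc(q, exposed_polar) > acc(s, exposed_polar)

    def test_confidence_higher_for_buried_sites(self, coupled_benchmark):
        from maskstack.evaluation import burial_confidence_gap, confidence_rsa_profile

        bench = coupled_benchmark
        ann = pd.concat(
            [
                pd.DataFrame(
                    {
                        "protein_id": rec.identifier,
                        "site": np.arange(1, len(rec) + 1),
                        "rsa": rec.rsa,
                    }
                )
                for rec in bench.proteins
            ],
            ignore_index=True,
        )
        for m in bench.model_ids:
            prof = confidence_rsa_profile(bench.predictions_for(m), ann)
            buried, exposed = burial_confidence_gap(prof)
            assert buried > exposed

    def test_expected_marginal_accounts_for_difficulty_clipping(self):
        prof = uniform_profile(
            "m", "structure", 0.9, difficulty_slope=0.4,
            protein_shared_sd=0.0, protein_common_sd=0.0, protein_own_sd=0.0,
        )
        spec = ProteinSimSpec(n_proteins=50, length_range=(200, 200))
        proteins = generate_proteins(spec, seed=31)
        expected = expected_marginal_accuracy(prof, proteins)
        # clipping at 0.98 trims the easy-site tail, so the true mean sits
        # below the nominal 0.9 cell value
        assert expected < 0.9
        bench = generate_benchmark(
            spec,
            [
                prof,
                uniform_profile("s2", "structure", 0.5),
                uniform_profile("q1", "sequence", 0.5),
                uniform_profile("q2", "sequence", 0.5),
            ],
            seed=31,
        )
        observed = add_call_columns(bench.predictions_for("m"))["correct"].mean()
        se = np.sqrt(expected * (1 - expected) / 10_000)
        assert abs(observed - expected) < 3 * se
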