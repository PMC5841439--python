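import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from splicedas.signatures import (
    PerturbationMeta,
    compare_signatures,
    conserved_event_regulators,
    disease_signature,
    perturbation_signature,
    sf_direction,
    size_factors,
)
from splicedas.simulate import (
    SimulationConfig,
    simulate_sf_perturbations,
    simulate_signature_pair,
)


def das_frame(delta_psi, q):
    return pd.DataFrame(
        {
            "event_id": [f"E{i}" for i in range(len(delta_psi))],
            "delta_psi": delta_psi,
            "q": q,
        }
    )


class TestSizeFactors:
    def test_identical_samples_get_unit_factors(self):
        m = pd.DataFrame({"s1": [10, 20, 5], "s2": [10, 20, 5]})
        assert np.allclose(size_factors(m), 1.0)

    def test_hand_worked_median_of_ratios(self):
        m = pd.DataFrame({"s1": [2, 2], "s2": [8, 8]})
        f = size_factors(m)
        assert np.allclose(f, [0.5, 2.0])

    def test_scaling_one_sample_scales_its_factor(self, rng):
        base = pd.DataFrame(rng.poisson(50, size=(30, 3)) + 1, columns=list("abc"))
        f0 = size_factors(base)
        scaled = base.copy()
        scaled["b"] = scaled["b"] * 3
        f1 = size_factors(scaled)
        # geometric means also shift, so compare the b:a factor ratio
        assert (f1["b"] / f1["a"]) / (f0["b"] / f0["a"]) == pytest.approx(3.0, rel=1e-9)

    def test_no_common_nonzero_gene_rejected(self):
        m = pd.DataFrame({"s1": [0, 5], "s2": [5, 0]})
        with pytest.raises(ValueError):
            size_factors(m)


class TestSfDirection:
    def test_doubled_case_mean_is_up(self):
        m = pd.DataFrame(
            {"c1": [100, 50], "c2": [100, 50], "n1": [50, 50], "n2": [50, 50]},
            index=["SF1", "other"],
        )
        assert sf_direction(m, "SF1", ["c1", "c2"], ["n1", "n2"]) == "up"

    def test_equal_means_undetermined(self):
        m = pd.DataFrame(
            {"c1": [50, 20], "n1": [50, 20]}, index=["SF1", "other"]
        )
        assert sf_direction(m, "SF1", ["c1"], ["n1"]) == "undetermined"

    def test_missing_gene_raises(self):
        m = pd.DataFrame({"c1": [1]}, index=["g"])
        with pytest.raises(KeyError):
            sf_direction(m, "SF1", ["c1"], ["c1"])

    def test_planted_knockdown_detected(self, rng):
        hits = 0
        for _ in range(100):
            base = rng.poisson(200, size=(10, 6)).astype(float)
            m = pd.DataFrame(
                base, index=[f"g{i}" for i in range(10)],
                columns=[f"c{i}" for i in range(3)] + [f"n{i}" for i in range(3)],
            )
            m.iloc[0, :3] = np.round(m.iloc[0, :3] / 3)
            hits += (
                sf_direction(m, "g0", ["c0", "c1", "c2"], ["n0", "n1", "n2"])
                == "down"
            )
        assert hits >= 99


class TestSignatureConstruction:
    def test_overexpression_keeps_raw_direction(self):
        das = das_frame([0.2, -0.2, 0.2], [0.01, 0.01, 0.2])
        sig = perturbation_signature(das, PerturbationMeta("d", "SF", "OE"))
        assert list(sig) == ["+", "-", "0"]

    def test_knockout_flips_direction(self):
        das = das_frame([-0.2, 0.2], [0.01, 0.01])
        sig = perturbation_signature(das, PerturbationMeta("d", "SF", "KO"))
        assert list(sig) == ["+", "-"]

    def test_insignificant_q_is_unchanged(self):
        das = das_frame([0.5], [0.2])
        sig = perturbation_signature(das, PerturbationMeta("d", "SF", "OE"))
        assert list(sig) == ["0"]

    def test_disease_signature_oriented_by_sf_direction(self):
        das = das_frame([0.2, -0.2], [0.01, 0.01])
        assert list(disease_signature(das, "up")) == ["+", "-"]
        assert list(disease_signature(das, "down")) == ["-", "+"]

    def test_undetermined_direction_rejected(self):
        with pytest.raises(ValueError):
            disease_signature(das_frame([0.2], [0.01]), "undetermined")

    def test_unknown_perturbation_direction_rejected(self):
        with pytest.raises(ValueError):
            PerturbationMeta("d", "SF", "sideways")


class TestCompareSignatures:
    def _sig(self, symbols):
        return pd.Series(list(symbols), index=[f"E{i}" for i in range(len(symbols))])

    def test_identical_signatures_enumeration(self):
        """5 +, 5 -, 10 zeros in perfect agreement: the ++ table is
        [[5,0],[0,15]], p = 1/C(20,5); same for --."""
        sig = self._sig("+" * 5 + "-" * 5 + "0" * 10)
        res = compare_signatures(sig, sig)
        expected = 1 / comb(20, 5, exact=True)
        assert res.p_pp == pytest.approx(expected, rel=1e-9)
        assert res.p_mm == pytest.approx(expected, rel=1e-9)
        assert res.candidate

    def test_all_zero_disease_is_degenerate(self):
        res = compare_signatures(self._sig("++--00"), self._sig("000000"))
        assert res.p_pp == 1.0 and res.p_mm == 1.0 and not res.candidate

    def test_collapse_preserves_totals(self):
        res = compare_signatures(self._sig("++--00+-"), self._sig("+-+-0+0-"))
        assert int(res.table.to_numpy().sum()) == 8

    def test_swap_transposes_table_and_keeps_p(self):
        a, b = self._sig("++--00+-"), self._sig("+-+-0+0-")
        r1 = compare_signatures(a, b)
        r2 = compare_signatures(b, a)
        assert (r1.table.to_numpy() == r2.table.to_numpy().T).all()
        assert r1.p_pp == pytest.approx(r2.p_pp)
        assert r1.p_mm == pytest.approx(r2.p_mm)

    def test_no_common_events_rejected(self):
        a = pd.Series(["+"], index=["E1"])
        b = pd.Series(["+"], index=["E2"])
        with pytest.raises(ValueError):
            compare_signatures(a, b)

    def test_permutation_null_candidate_rate(self, rng):
        """Independent signatures: the AND rule calls candidates at roughly
        alpha squared, so well under alpha + 2 SE for 200 replicates."""
        alpha = 0.05
        calls = 0
        n_rep = 200
        for _ in range(n_rep):
            p, d, _ = simulate_signature_pair(100, 0.0, rng)
            calls += compare_signatures(p, d, alpha=alpha).candidate
        se = np.sqrt(alpha * (1 - alpha) / n_rep)
        assert calls / n_rep <= alpha + 2 * se


class TestRegulatorAttribution:
    def test_agreeing_nonzero_symbols_attributed(self):
        psig = pd.Series(["+", "+", "-", "0"], index=list("abcd"))
        dsig = pd.Series(["+", "-", "-", "+"], index=list("abcd"))
        out = conserved_event_regulators(list("abcd"), {"SF": psig}, {"SF": dsig})
        assert out == {"SF": ["a", "c"]}

    def test_zero_symbols_never_attributed(self):
        psig = pd.Series(["0"], index=["a"])
        dsig = pd.Series(["0"], index=["a"])
        assert conserved_event_regulators(["a"], {"SF": psig}, {"SF": dsig}) == {}


class TestEndToEndPerturbationSimulation:
    def test_full_overlap_gives_overwhelming_evidence(self, rng):
        """Planted SF with its whole regulon mirrored in disease over 100+
        common events: both one-sided tests essentially reject outright."""
        cfg = SimulationConfig(
            seed=2, n_sfs=1, regulon_size=60, signature_overlap=1.0,
            depth_mean=300.0, theta=80.0,
        )
        events = [f"E{i}" for i in range(150)]
        data = simulate_sf_perturbations(cfg, events, rng=rng)
        from splicedas.dasmodel import call_das, run_das

        (ds,) = data["perturbations"].values()
        pert_das = call_das(run_das(ds["counts"], "perturbed", "control"))
        psig = perturbation_signature(pert_das, ds["meta"])
        disease_das = call_das(run_das(data["disease"]["counts"], "case", "control"))
        sf = ds["meta"].sf_gene
        dsig = disease_signature(disease_das, data["disease"]["sf_directions"][sf])
        res = compare_signatures(psig, dsig)
        assert res.p_pp < 1e-6 and res.p_mm < 1e-6 and res.candidate

    def test_planted_ko_regulon_signature_sign(self, rng):
        """A KO dataset down-shifts the positively regulated events; the
        perturbation signature must read them back as +."""
        cfg = SimulationConfig(
            seed=4, n_sfs=2, regulon_size=30, depth_mean=300.0, theta=80.0
        )
        events = [f"E{i}" for i in range(80)]
        data = simulate_sf_perturbations(cfg, events, rng=rng)
        from splicedas.dasmodel import call_das, run_das

        ko_ds = next(
            ds for ds in data["perturbations"].values()
            if ds["meta"].direction in ("KO", "KD")
        )
        pert_das = call_das(run_das(ko_ds["counts"], "perturbed", "control"))
        psig = perturbation_signature(pert_das, ko_ds["meta"])
        regulon = data["truth"][ko_ds["meta"].sf_gene]
        correct = sum(
            psig.get(e) == ("+" if s > 0 else "-") for e, s in regulon.items()
        )
        assert correct >= 0.8 * len(regulon)
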