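"""Synthetic generators: determinism, geometry, planted effects, validation."""

import numpy as np
import pandas as pd
import pytest

import villustat as vs
from villustat.signatures import CELL_TYPE_SIGNATURES

from conftest import tiny_tissue


class TestTissueDeterminism:
    def test_same_seed_identical_output(self):
        cfg = tiny_tissue(seed=11)
        s1, c1, g1 = vs.simulate_section(cfg)
        s2, c2, g2 = vs.simulate_section(cfg)
        pd.testing.assert_frame_equal(s1, s2)
        assert (c1.X != c2.X).nnz == 0
        assert list(c1.var_names) == list(c2.var_names)
        assert g1 == g2

    def test_different_seed_differs(self):
        s1, c1, _ = vs.simulate_section(tiny_tissue(seed=1))
        s2, c2, _ = vs.simulate_section(tiny_tissue(seed=2))
        assert (c1.X != c2.X).nnz > 0


class TestTissueGeometry:
    def test_compartment_bands_and_bounds(self, small_section):
        cfg, spots, _, _ = small_section
        assert spots["spot_id"].is_unique
        assert (spots["x_um"] >= 0).all() and (spots["x_um"] <= cfg.section_width_um).all()
        assert (spots["y_um"] >= 0).all() and (spots["y_um"] <= cfg.section_height_um).all()
        sm = spots[spots["compartment"] == "smooth_muscle"]
        assert (sm["y_um"] < cfg.muscle_band_um).all()
        crypt = spots[spots["compartment"] == "crypt"]
        assert (crypt["y_um"] >= cfg.muscle_band_um).all()
        assert (crypt["y_um"] < cfg.muscle_band_um + cfg.crypt_band_um).all()

    def test_immune_labels_only_on_stroma_and_crypt(self, small_section):
        _, spots, _, _ = small_section
        labelled = spots[spots["cell_type"] != ""]
        assert set(labelled["compartment"]) <= {"crypt", "lamina_propria"}

    def test_all_compartments_present(self, small_section):
        _, spots, _, _ = small_section
        assert {"smooth_muscle", "crypt", "enterocyte",
                "lamina_propria"} <= set(spots["compartment"])


class TestPlantedEffects:
    def test_unit_enrichment_gives_flat_crypt_density(self):
        """With crypt_enrichment=1 everywhere, pooled CD8T density in the crypt
        zone matches the outside density within binomial sampling error."""
        k_in = n_in = k_out = n_out = 0
        for seed in range(20):
            cfg = tiny_tissue(seed=seed)
            spots, _, _ = vs.simulate_section(cfg)
            eligible = spots["compartment"].isin(["crypt", "lamina_propria"])
            zone = (spots["y_um"] >= cfg.muscle_band_um) & (
                spots["y_um"] < cfg.muscle_band_um + cfg.crypt_band_um)
            cd8 = spots["cell_type"] == "CD8T"
            k_in += int((cd8 & eligible & zone).sum())
            n_in += int((eligible & zone).sum())
            k_out += int((cd8 & eligible & ~zone).sum())
            n_out += int((eligible & ~zone).sum())
        p_in, p_out = k_in / n_in, k_out / n_out
        se = np.sqrt(p_in * (1 - p_in) / n_in + p_out * (1 - p_out) / n_out)
        assert abs(p_in - p_out) < 4 * se

    def test_planted_enrichment_raises_crypt_density(self):
        cfg = tiny_tissue(seed=3, crypt_enrichment={"CD8T": 3.0})
        _, _, gt = vs.simulate_section(cfg)
        d = gt["realized_density"]["CD8T"]
        assert d["crypt_zone"] > 1.5 * d["outside"]

    def test_flat_signature_fc_equalizes_means(self):
        """With signature_fc=1 and matching proliferation fold, marker-gene
        and filler-gene mean counts agree within NB sampling error."""
        sig_means, filler_means = [], []
        for seed in range(10):
            cfg = tiny_tissue(seed=seed, signature_fc=1.0,
                              crypt_proliferation_fc=1.0)
            _, counts, _ = vs.simulate_section(cfg)
            named = [g for g in counts.var_names if not g.startswith("G")]
            filler = [g for g in counts.var_names if g.startswith("G")]
            sig_means.append(float(counts[:, named].X.mean()))
            filler_means.append(float(counts[:, filler].X.mean()))
        diff = np.mean(sig_means) - np.mean(filler_means)
        pooled_sd = np.std(np.array(sig_means) - np.array(filler_means), ddof=1)
        assert abs(diff) < 4 * pooled_sd / np.sqrt(len(sig_means))

    def test_signature_fc_raises_marker_counts(self, small_section):
        _, spots, counts, _ = small_section
        m1_spots = spots.loc[spots["cell_type"] == "M1", "spot_id"].tolist()
        bg_spots = spots.loc[spots["cell_type"] == "", "spot_id"].tolist()[:500]
        genes = sorted(CELL_TYPE_SIGNATURES["M1"].genes)
        m1_mean = float(counts[m1_spots, genes].X.mean())
        bg_mean = float(counts[bg_spots, genes].X.mean())
        assert m1_mean > 2 * bg_mean

    def test_nb_marginal_mean_converges(self):
        cfg = tiny_tissue(seed=5, section_width_um=460.0, section_height_um=120.0,
                          signature_fc=1.0, crypt_proliferation_fc=1.0)
        spots, counts, _ = vs.simulate_section(cfg)
        assert len(spots) >= 10_000
        mean = float(counts.X.mean())
        assert abs(mean - cfg.nb_mean) / cfg.nb_mean < 0.05


class TestTissueValidation:
    @pytest.mark.parametrize(
        "overrides, field",
        [
            ({"spot_pitch_um": 0.0}, "spot_pitch_um"),
            ({"muscle_band_um": 60.0, "crypt_band_um": 60.0}, "crypt_band_um"),
            ({"immune_spot_fraction": {"CD8T": 1.5}}, "immune_spot_fraction"),
            ({"crypt_enrichment": {"CD8T": -1.0}}, "crypt_enrichment"),
            ({"n_genes": 5}, "n_genes"),
            ({"crypt_enrichment": {"M1": 30.0}, "cd8_m1_coloc": 10.0},
             "crypt_enrichment"),
        ],
    )
    def test_invalid_config_names_field(self, overrides, field):
        cfg = tiny_tissue(**overrides)
        with pytest.raises(vs.ValidationError, match=field):
            vs.simulate_section(cfg)


class TestComposition:
    PROBS = {"A": 0.5, "B": 0.3, "C": 0.2}

    def test_identical_probs_give_unit_roe(self):
        """Same subset probabilities in both groups: every Ro/e is ~1."""
        worst = 0.0
        for seed in range(20):
            comp = vs.simulate_composition(
                {"g1_s1": 5000, "g2_s1": 5000},
                {"g1": self.PROBS, "g2": self.PROBS},
                {"g1_s1": "g1", "g2_s1": "g2"},
                seed=seed,
            )
            roe = vs.roe_scores(comp).roe
            worst = max(worst, float((roe - 1.0).abs().max().max()))
        assert worst < 0.1

    def test_zero_probability_subset_absent(self):
        comp = vs.simulate_composition(
            {"s": 2000}, {"g": {"A": 1.0, "B": 0.0}}, {"s": "g"}, seed=0)
        assert (comp["subset"] == "B").sum() == 0

    def test_seed_reproducibility(self):
        kw = dict(n_per_sample={"s": 500}, subset_probs={"g": self.PROBS},
                  sample_groups={"s": "g"}, seed=9)
        pd.testing.assert_frame_equal(vs.simulate_composition(**kw),
                                      vs.simulate_composition(**kw))

    def test_bad_probabilities_rejected(self):
        with pytest.raises(vs.ValidationError, match="sum"):
            vs.simulate_composition({"s": 10}, {"g": {"A": 0.6, "B": 0.6}},
                                    {"s": "g"})


class TestRepertoire:
    def test_no_expansion_all_singletons(self):
        cfg = vs.RepertoireConfig(
            n_cells_per_subset={"CD8_Teff": 200}, expansion_prob={"CD8_Teff": 0.0},
            seed=0)
        rep = vs.simulate_repertoire(cfg)
        sizes = rep.groupby("clonotype_id").size()
        assert (sizes == 1).all()
        assert vs.gini_index(sizes.to_numpy()) == 0.0

    def test_full_expansion_fixed_size_entropy(self):
        n, k = 120, 4
        cfg = vs.RepertoireConfig(
            n_cells_per_subset={"CD8_Teff": n}, expansion_prob={"CD8_Teff": 1.0},
            expanded_clone_size_dist=("fixed", k), seed=0)
        rep = vs.simulate_repertoire(cfg)
        sizes = rep.groupby("clonotype_id").size().to_numpy()
        assert set(sizes) == {k}
        assert vs.shannon_entropy(sizes) == pytest.approx(np.log(n / k))

    def test_planted_teff_expansion_recovered_every_seed(self):
        """CD8 Teff expanded-cell fraction beats all other subsets, 20/20 seeds."""
        for seed in range(20):
            rep = vs.simulate_repertoire(vs.cko_like_repertoire(seed=seed))
            classes = vs.clonal_size_classes(rep)
            exp = (classes[classes["expanded"]]
                   .set_index("subset")["fraction"])
            assert exp["CD8_Teff"] == exp.max()
            assert (exp.drop("CD8_Teff") < exp["CD8_Teff"]).all()

    def test_empty_subset_map_rejected(self):
        with pytest.raises(vs.ValidationError, match="n_cells_per_subset"):
            vs.RepertoireConfig(n_cells_per_subset={}, expansion_prob={}).validate()

    def test_expanded_clones_have_size_at_least_two(self):
        rep = vs.simulate_repertoire(vs.cko_like_repertoire(seed=4))
        sizes = rep.groupby(["sample", "clonotype_id"]).size()
        expanded_ids = [c for (_, c) in sizes.index if "_e" in c]
        assert all(sizes[(s, c)] >= 1 for (s, c) in sizes.index)
        exp_sizes = sizes[[idx for idx in sizes.index if "_e" in idx[1]]]
        # trimming can leave at most one clone per subset below 2
        assert (exp_sizes >= 2).mean() > 0.9
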