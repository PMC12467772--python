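"""Generator contracts: determinism, planted-match exactness, parameter recovery."""

import numpy as np
import pytest

from ota_sentinel.simulate import (ConfigError, PathwaySpec, PlantedMatch,
                                   SimulationConfig, config_from_yaml,
                                   config_to_yaml, demo_config, gen_counts,
                                   gen_pathways,
                                   gen_transcriptome_with_planted_matches,
                                   write_dataset)
from ota_sentinel.matchscan import lcs_length_both_strands
from ota_sentinel.offtarget import pathway_levels
from ota_sentinel.sequences import gen_dsrna

from test_matchscan import oracle_max_match


def small_cfg(**kw):
    defaults = dict(seed=1, n_genes=40, gene_length_range=(100, 200),
                    dsrna_length=100, stages=("larva",),
                    pathway_spec=PathwaySpec(n_pathways=3, genes_per_pathway=8,
                                             overlap_fraction=0.25))
    defaults.update(kw)
    return SimulationConfig(**defaults)


def test_planted_classes_exact_against_independent_oracle():
    cfg = small_cfg(planted_matches=(PlantedMatch(8, 10, "sense"),
                                     PlantedMatch(15, 1, "sense")))
    construct = gen_dsrna(cfg.dsrna_length, cfg.seed)
    records, truth = gen_transcriptome_with_planted_matches(cfg, construct)
    by_id = dict(records)
    for row in truth.itertuples():
        assert oracle_max_match(by_id[row.gene_id], construct) == row.oracle_max
        if row.planted_length:
            assert row.oracle_max == row.planted_length
        else:
            assert row.oracle_max < 7
    assert (truth.planted_length == 8).sum() == 10
    assert (truth.planted_length == 15).sum() == 1


def test_antisense_planting_hits_the_antisense_branch():
    cfg = small_cfg(planted_matches=(PlantedMatch(12, 5, "antisense"),))
    construct = gen_dsrna(cfg.dsrna_length, cfg.seed)
    records, truth = gen_transcriptome_with_planted_matches(cfg, construct)
    by_id = dict(records)
    planted = truth[truth.planted_length == 12]
    assert len(planted) == 5
    for row in planted.itertuples():
        gene = by_id[row.gene_id]
        assert lcs_length_both_strands(gene, construct) == 12


def test_background_only_transcriptome_stays_below_floor():
    cfg = small_cfg(planted_matches=())
    construct = gen_dsrna(cfg.dsrna_length, cfg.seed)
    _, truth = gen_transcriptome_with_planted_matches(cfg, construct)
    assert (truth.oracle_max < 7).all()


def test_transcriptome_is_deterministic():
    cfg = small_cfg(planted_matches=(PlantedMatch(9, 3, "sense"),))
    construct = gen_dsrna(cfg.dsrna_length, cfg.seed)
    a, _ = gen_transcriptome_with_planted_matches(cfg, construct)
    b, _ = gen_transcriptome_with_planted_matches(cfg, construct)
    assert a == b


@pytest.mark.parametrize("kw,msg", [
    (dict(planted_matches=(PlantedMatch(150, 1, "sense"),)), "exceeds"),
    (dict(nb_dispersion=0.0), "dispersion"),
    (dict(n_replicates=1), "replicates"),
    (dict(planted_matches=(PlantedMatch(7, 100, "sense"),)), "planted"),
])
def test_infeasible_configs_rejected(kw, msg):
    with pytest.raises(ConfigError, match=msg):
        small_cfg(**kw)


def test_planting_below_background_floor_rejected():
    with pytest.raises(ConfigError, match="floor"):
        small_cfg(planted_matches=(PlantedMatch(5, 1, "sense"),))


def test_counts_null_ratio_near_one():
    cfg = small_cfg(n_genes=200, nb_dispersion=0.01, n_replicates=30,
                    nb_mean_log_range=(2.0, 3.0))
    counts, sheet, truth = gen_counts(cfg)
    assert truth.empty
    t = sheet[sheet.group == "treatment"].sample_id
    c = sheet[sheet.group == "control"].sample_id
    ratio = counts[list(t)].mean(axis=1) / counts[list(c)].mean(axis=1)
    assert np.abs(np.log2(ratio)).mean() < 0.1


def test_planted_fold_change_shifts_the_mean():
    """A +3 log2FC gene's treatment mean lands near 8x its control mean."""
    cfg = small_cfg(n_genes=5, nb_dispersion=0.05, n_replicates=1000,
                    nb_mean_log_range=(2.0, 2.0),  # all baselines exactly 100
                    planted_degs={"larva": [("g0001", 3.0)]})
    counts, sheet, _ = gen_counts(cfg)
    t = counts.loc["g0001", list(sheet[sheet.group == "treatment"].sample_id)]
    c = counts.loc["g0001", list(sheet[sheet.group == "control"].sample_id)]
    # mean 800, sd = sqrt(800 + 0.05*800^2) ~ 180 -> 3 SE over 1000 reps ~ 17
    assert abs(t.mean() - 800) < 3 * np.sqrt(800 + 0.05 * 800**2) / np.sqrt(1000)
    assert abs(c.mean() - 100) < 3 * np.sqrt(100 + 0.05 * 100**2) / np.sqrt(1000)


def test_counts_deterministic():
    cfg = small_cfg()
    a, _, _ = gen_counts(cfg)
    b, _, _ = gen_counts(cfg)
    assert a.equals(b)


def test_pathway_chain_realises_intended_levels():
    """BFS levels computed from the generated sets equal the intended map."""
    cfg = small_cfg(pathway_spec=PathwaySpec(n_pathways=3, genes_per_pathway=6,
                                             overlap_fraction=0.25,
                                             seed_gene="g0005"))
    pathways, intended = gen_pathways(cfg)
    realised = pathway_levels(pathways, {"g0005"}, max_level=3)
    assert realised == intended


def test_disjoint_pathways_only_level_one():
    cfg = small_cfg(pathway_spec=PathwaySpec(n_pathways=3, genes_per_pathway=5,
                                             overlap_fraction=0.0,
                                             seed_gene="g0001"))
    pathways, intended = gen_pathways(cfg)
    assert set(intended.values()) == {1}
    assert set(intended) == set(pathways["PW0001"])


def test_seed_gene_absent_gives_empty_intended_map():
    cfg = small_cfg(pathway_spec=PathwaySpec(n_pathways=2, genes_per_pathway=5,
                                             overlap_fraction=0.2,
                                             seed_gene="g0001",
                                             place_seed=False))
    pathways, intended = gen_pathways(cfg)
    assert intended == {}
    assert all("g0001" not in members for members in pathways.values())


def test_config_yaml_round_trip():
    cfg = demo_config(seed=3)
    assert config_from_yaml(config_to_yaml(cfg)) == cfg


def test_write_dataset_byte_identical_across_runs(tmp_path):
    cfg = small_cfg(planted_matches=(PlantedMatch(8, 2, "sense"),),
                    planted_degs={"larva": [("g0003", 2.0)]})
    p1 = write_dataset(cfg, tmp_path / "a")
    p2 = write_dataset(cfg, tmp_path / "b")
    for name in p1:
        assert p1[name].read_bytes() == p2[name].read_bytes(), name
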