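import numpy as np
import pytest

from ota_sentinel.sequences import gen_dsrna
from ota_sentinel.simulate import demo_config, gen_counts, gen_pathways, \
    gen_transcriptome_with_planted_matches


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture(scope="session")
def demo():
    """The seeded demo dataset: construct, transcriptome, counts, pathways."""
    cfg = demo_config(seed=7)
    construct = gen_dsrna(cfg.dsrna_length, cfg.seed, construct_id="ds_construct")
    transcriptome, truth_matches = gen_transcriptome_with_planted_matches(cfg, construct)
    counts, sample_sheet, truth_degs = gen_counts(cfg)
    pathways, intended_levels = gen_pathways(cfg)
    return {
        "config": cfg,
        "construct": construct,
        "transcriptome": transcriptome,
        "truth_matches": truth_matches,
        "counts": counts,
        "sample_sheet": sample_sheet,
        "truth_degs": truth_degs,
        "pathways": pathways,
        "intended_levels": intended_levels,
    }
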