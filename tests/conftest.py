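import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """One full pipeline run on the default synthetic experiment."""
    from sortmave.pipeline import PipelineConfig, run_pipeline

    outdir = tmp_path_factory.mktemp("pipeline")
    return run_pipeline(PipelineConfig(seed=11), outdir)


@pytest.fixture(scope="session")
def null_experiment():
    """A small experiment in which every variant effect is exactly zero."""
    from sortmave import synthetic_data as sd
    from sortmave.library_design import Region, enumerate_possible_variants

    region = Region(28, 127)
    wt_seq = sd.random_protein_sequence(len(region), seed=5, start_pos=28,
                                        pin_controls=False)
    variants = enumerate_possible_variants(region, wt_seq,
                                           include_nonsense=False)[:300]
    effects = sd.sample_true_effects(
        variants, sd.EffectConfig(lof_fraction=0.0, gof_fraction=0.0), seed=5
    )
    bvmap = sd.build_barcode_variant_map(effects, barcodes_per_variant=2, seed=5)
    config = sd.SortSimConfig(replicates={"bind_insulin": 3}, seed=5)
    counts = sd.simulate_experiment(effects, bvmap, config, ["bind_insulin"])
    return effects, bvmap, counts


@pytest.fixture()
def tiny_map():
    """Four barcodes over two variants plus two WT reference barcodes."""
    return pd.DataFrame(
        {
            "barcode": ["A" * 30, "C" * 30, "G" * 30, "T" * 30,
                        ("AC" * 15), ("GT" * 15)],
            "position": [100, 100, 200, 200, 0, 0],
            "wt_aa": ["G", "G", "W", "W", "=", "="],
            "alt_aa": ["Q", "Q", "*", "*", "=", "="],
            "support_reads": [5, 4, 3, 2, 10, 9],
        }
    )
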