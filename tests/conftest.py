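from __future__ import annotations

import pytest

from txatlas import pipeline, synthetic_data as sd


@pytest.fixture(scope="session")
def ts_config() -> sd.SyntheticConfig:
    return sd.SyntheticConfig.test_scale(seed=1)


@pytest.fixture(scope="session")
def ts_dataset(ts_config) -> sd.SyntheticDataset:
    """~50 Mb synthetic chromosome, generated once per session."""
    return sd.generate_chromosome(ts_config)


@pytest.fixture(scope="session")
def ts_paths(ts_dataset, tmp_path_factory) -> dict:
    outdir = tmp_path_factory.mktemp("dataset")
    return sd.write_dataset(ts_dataset, outdir)


@pytest.fixture()
def run_config(ts_paths, tmp_path) -> pipeline.RunConfig:
    return pipeline.RunConfig(
        gff3=str(ts_paths["gff3"]),
        fpkm=str(ts_paths["matrix"]),
        fasta=str(ts_paths["fasta"]),
        antisense=str(ts_paths["antisense"]),
        ntr_bed=str(ts_paths["ntr_bed"]),
        similarity=str(ts_paths["similarity"]),
        outdir=str(tmp_path / "run"),
    )
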