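from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from g4scape import RunConfig, SynthSpec, generate, run_pipeline

FIXTURE_SEED = 20260


@pytest.fixture(scope="session")
def synth_dataset(tmp_path_factory):
    """Default-condition synthetic genome, written to disk once per session."""
    out = tmp_path_factory.mktemp("synth")
    dataset = generate(SynthSpec(seed=FIXTURE_SEED), out_dir=out)
    dataset.paths = {
        "fasta": out / "genome.fa",
        "gff": out / "annotation.gff3",
        "deg": out / f"deg_{dataset.spec.timepoint}.tsv",
        "dir": out,
    }
    return dataset


@pytest.fixture(scope="session")
def pipeline_run(synth_dataset, tmp_path_factory):
    """Full pipeline output on the session fixture genome."""
    out = tmp_path_factory.mktemp("run")
    cfg = RunConfig(
        fasta=str(synth_dataset.paths["fasta"]),
        gff=str(synth_dataset.paths["gff"]),
        out_dir=str(out / "run"),
        deg_tables={synth_dataset.spec.timepoint: str(synth_dataset.paths["deg"])},
        track_window=50_000,
        seed=FIXTURE_SEED,
    )
    return run_pipeline(cfg)


def random_sequence(rng: np.random.Generator, length: int, n_frac: float = 0.0) -> str:
    bases = np.array(list("ACGT"))
    seq = bases[rng.integers(0, 4, size=length)]
    if n_frac > 0:
        mask = rng.random(length) < n_frac
        seq[mask] = "N"
    return "".join(seq)
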