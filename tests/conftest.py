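import numpy as np
import pandas as pd
import pytest

from hopstat import ExpressionMatrix, Genotype, SampleMetadata, Stage
from hopstat.differential import DirectionalSets


def make_samples(replicates: int = 2) -> list[SampleMetadata]:
    """Full genotype panel with stage-matched WT controls."""
    samples = []
    for stage in (Stage.E0_12, Stage.E1_2):
        for r in range(1, replicates + 1):
            samples.append(
                SampleMetadata(f"WT_{stage.value}_r{r}", Genotype.WT, stage, r)
            )
    for g, stage in [
        (Genotype.JAK_GOF, Stage.E0_12),
        (Genotype.JAK_LOF, Stage.E0_12),
        (Genotype.STAT_HET, Stage.E0_12),
        (Genotype.STAT_MATNULL, Stage.E1_2),
    ]:
        for r in range(1, replicates + 1):
            samples.append(SampleMetadata(f"{g.value}_r{r}", g, stage, r))
    return samples


def make_matrix(
    intensity_rows: dict[str, list[float]],
    calls_rows: dict[str, list[str]] | None = None,
    samples: list[SampleMetadata] | None = None,
) -> ExpressionMatrix:
    samples = samples or make_samples()
    ids = [s.sample_id for s in samples]
    intensity = pd.DataFrame.from_dict(intensity_rows, orient="index", columns=ids)
    intensity.index.name = "probe_id"
    if calls_rows is None:
        calls = pd.DataFrame("P", index=intensity.index, columns=ids)
    else:
        calls = pd.DataFrame.from_dict(calls_rows, orient="index", columns=ids)
        calls.index.name = "probe_id"
    return ExpressionMatrix(intensity=intensity, calls=calls, samples=samples)


def dirsets(genotype, up=(), down=()) -> DirectionalSets:
    return DirectionalSets(
        mutant=Genotype(genotype), up=frozenset(up), down=frozenset(down)
    )


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """Three probes, constant 100 everywhere except probe p_up (400 in
    JAK_GOF) and p_down (25 in JAK_GOF)."""
    samples = make_samples()
    base = {f"p{i}": [100.0] * len(samples) for i in range(3)}
    m = make_matrix(base, samples=samples)
    gof = [s.sample_id for s in samples if s.genotype is Genotype.JAK_GOF]
    m.intensity.loc["p1", gof] = 400.0
    m.intensity.loc["p2", gof] = 25.0
    return m
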