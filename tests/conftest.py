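"""Shared fixtures.

The expensive fixture is ``cohort``: the full default synthetic study
(42 stimulation / 62 control recordings, 600 s each) pushed through
resampling, EMD and band recombination once per session, with
endpoint-difference features precomputed at the six experiment window
sizes.  Everything else is small and per-test.
"""

from __future__ import annotations

import numpy as np
import pytest

from hrvnoci import (
    SynthConfig,
    UniformSeries,
    endpoint_difference,
    generate_dataset,
    generate_recording,
    selected_sizes,
)
from hrvnoci.features import WindowConfig
from hrvnoci.pipeline import PipelineConfig, process_recording

COHORT_SEED = 1


@pytest.fixture(scope="session")
def pipeline_cfg() -> PipelineConfig:
    return PipelineConfig(seed=COHORT_SEED)


@pytest.fixture(scope="session")
def cohort(pipeline_cfg):
    """Default synthetic cohort with all pipeline products precomputed."""
    dataset = generate_dataset(seed=COHORT_SEED)
    tachograms, decompositions, components = [], [], []
    features_by_size: dict[int, list] = {s: [] for s in selected_sizes()}
    for rec in dataset.recordings:
        tach, d, comp = process_recording(rec, pipeline_cfg)
        tachograms.append(tach)
        decompositions.append(d)
        components.append(comp)
        for s in selected_sizes():
            features_by_size[s].append(
                endpoint_difference(comp.lf, WindowConfig(s),
                                    source_id=rec.recording_id)
            )
    return {
        "dataset": dataset,
        "labels": dataset.labels,
        "tachograms": tachograms,
        "decompositions": decompositions,
        "components": components,
        "features_by_size": features_by_size,
    }


@pytest.fixture(scope="session")
def two_tone() -> dict:
    """sin(2*pi*0.25 t) + 0.5 sin(2*pi*0.05 t), 8 Hz, 600 s."""
    fs = 8.0
    t = np.arange(0.0, 600.0, 1.0 / fs)
    hf = np.sin(2 * np.pi * 0.25 * t)
    lf = 0.5 * np.sin(2 * np.pi * 0.05 * t)
    return {
        "t": t,
        "hf": hf,
        "lf": lf,
        "series": UniformSeries(hf + lf, sampling_rate_hz=fs),
    }


@pytest.fixture(scope="session")
def t1_components(pipeline_cfg):
    """One noise-free T1 recording pushed through the pipeline."""
    cfg = SynthConfig(noise_sd_ms=0.0, seed=11)
    rec = generate_recording(cfg, "T1")
    _, _, comp = process_recording(rec, pipeline_cfg)
    return comp
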