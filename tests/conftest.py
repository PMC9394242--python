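import numpy as np
import pytest

from dictatime import GeneratorConfig, generate_durations

# generator config used by most mixture tests: Normal(16, 5) with weight 0.9
# plus a uniform background on (0, 240]
UNIFORM_MIX = dict(weights=(0.0, 0.9, 0.0, 0.1), unknown_range=(0.0, 240.0))


@pytest.fixture(scope="session")
def mix_sample_5000():
    """n = 5000 draws from Normal(16,5) w=0.9 + Uniform(0,240] w=0.1."""
    cfg = GeneratorConfig(n=5000, seed=3, **UNIFORM_MIX)
    return generate_durations(cfg).durations


@pytest.fixture(scope="session")
def mix_sample_500():
    cfg = GeneratorConfig(n=500, seed=5, **UNIFORM_MIX)
    return generate_durations(cfg).durations


@pytest.fixture()
def timestamps_csv(tmp_path):
    """Factory writing a small hand-rolled timestamp CSV."""

    def _write(rows, header="exam_id,region_code,dictation_start,first_save"):
        path = tmp_path / "timestamps.csv"
        path.write_text("\n".join([header, *rows]) + "\n", encoding="utf-8")
        return path

    return _write
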