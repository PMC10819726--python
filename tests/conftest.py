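import numpy as np
import pytest

from pigcall.audio import AudioClip
from pigcall.features import FeatureConfig
from pigcall.synthetic import SyntheticDatasetSpec, default_presets, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def feature_cfg():
    return FeatureConfig()


@pytest.fixture
def sine_clip():
    """1 kHz unit sine, 0.5 s at 44.1 kHz."""
    sr = 44100
    t = np.arange(int(0.5 * sr)) / sr
    return AudioClip(np.sin(2 * np.pi * 1000.0 * t), sr, id="sine1k")


@pytest.fixture
def noise_clip():
    sr = 44100
    gen = np.random.default_rng(99)
    return AudioClip(0.3 * gen.standard_normal(sr // 2), sr, id="noise")


@pytest.fixture(scope="session")
def small_clipset():
    """12 clips per class: enough for pipeline tests, fast to extract."""
    return generate_dataset(SyntheticDatasetSpec(class_counts=(12, 12, 12), seed=2024))


@pytest.fixture(scope="session")
def small_feature_table(small_clipset):
    from pigcall.features import extract_features, features_to_frame

    vectors = []
    for clip in small_clipset:
        try:
            vectors.append(extract_features(clip))
        except Exception:
            continue
    return features_to_frame(vectors)
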