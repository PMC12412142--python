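import pytest

from hramsst import default_panel
from hramsst.simulate import SyntheticRunConfig, generate_run


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def clean_pos_run(panel):
    """Noise-free positive-mode synthetic run with zero mass bias."""
    config = SyntheticRunConfig(panel=panel, polarity="POS", true_bias_ppm=0.0, seed=11)
    run, truth = generate_run(config)
    return run, truth


@pytest.fixture
def pos_mzml(tmp_path, clean_pos_run):
    from hramsst import write_mzml

    run, _ = clean_pos_run
    path = tmp_path / "clean_pos.mzML"
    write_mzml(run, path)
    return path
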