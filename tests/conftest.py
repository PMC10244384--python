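import numpy as np
import pytest

import tcravidity as tv


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_panel():
    """Six handwritten clonotypes spanning lengths 11-16."""
    return [
        tv.TcrClonotype("T1", "CASSLAPGATNEKLFF", halflife_s=120.0, pmhc="A"),
        tv.TcrClonotype("T2", "CASSLAPGATNEQYFF", halflife_s=80.0, pmhc="A"),
        tv.TcrClonotype("T3", "CASSPDRGHEQYF", halflife_s=5.0, pmhc="B"),
        tv.TcrClonotype("T4", "CASRGQGWDEKLF", halflife_s=30.0, pmhc="B"),
        tv.TcrClonotype("T5", "CASSFGREYEQYF", halflife_s=8.0, pmhc="C"),
        tv.TcrClonotype("T6", "CSARDWGNTIYF", halflife_s=90.0, pmhc="C"),
    ]


@pytest.fixture
def panel48():
    """Default-condition panel: 48 clonotypes, 11 high avidity."""
    return tv.generate_panel(tv.PanelSpec(seed=3, coupled_exposure=True))


def random_cdr3(rng, length):
    return "".join(tv.AA_ALPHABET[i] for i in rng.integers(0, 20, size=length))
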