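import numpy as np
import pytest

from tricontrast.sld_core import Component, ExchangeModel, preset
from tricontrast.synthetic_data import HTL_LIKE_SEQUENCE, make_fixture_suite


@pytest.fixture(scope="session")
def ddm():
    return preset("ddm")


@pytest.fixture(scope="session")
def lipid_mix():
    return preset("ecoli_inner_membrane_lipid")


@pytest.fixture(scope="session")
def protein():
    return Component.protein_from_sequences("htl_like", [HTL_LIKE_SEQUENCE])


@pytest.fixture(scope="session")
def exchange():
    return ExchangeModel()


@pytest.fixture(scope="session")
def htl_bundle():
    """Noisy (5% at I(0)) native-composition core-shell contrast series."""
    return make_fixture_suite("htl_native_like", seed=3, noise_rel_I0=0.05)


@pytest.fixture(scope="session")
def htl_bundle_clean():
    """Noise-free native-composition core-shell contrast series."""
    return make_fixture_suite("htl_native_like", seed=3, noise_rel_I0=0.0)


def guinier_points(bundle, **kwargs):
    """Guinier-fit a bundle's curves into ContrastPoint objects."""
    from tricontrast.contrast_series import ContrastPoint
    from tricontrast.guinier import guinier_fit

    pts = []
    for c in bundle.curves:
        res = guinier_fit(c, **kwargs)
        md = c.metadata
        pts.append(
            ContrastPoint(
                f_d2o=md["f_d2o"],
                guinier=res,
                concentration=md["concentration_mg_ml"],
                transmission=md["transmission"],
                path_length=md["path_length_cm"],
                intensity_scale=md.get("intensity_scale", "absolute"),
            )
        )
    return pts
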