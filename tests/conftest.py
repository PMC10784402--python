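import pytest

from soilleach import ApplicationEvent, PesticideParams, SoilLayer

# Andisol profile parameterised for dimethomorph: bulk density, batch
# adsorption/desorption fractions, first-order degradation rates, and the
# field bromide arrival days at each layer's bottom boundary.
DIMETHOMORPH_LAYERS = [
    ("SL1", 0.0, 0.2, 0.48, 0.933, 0.039, 0.039, 1),
    ("SL2", 0.2, 0.4, 0.57, 0.930, 0.037, 0.010, 43),
    ("SL3", 0.4, 0.6, 0.64, 0.903, 0.058, 0.009, 93),
    ("SL4", 0.6, 0.8, 0.71, 0.786, 0.131, 0.009, 255),
    ("SL5", 0.8, 1.0, 0.67, 0.675, 0.177, 0.001, None),
]


@pytest.fixture
def andisol_profile():
    return [
        SoilLayer(
            layer_id=lid,
            top_depth=top,
            bottom_depth=bot,
            rho_b=rho,
            f_ads=fa,
            f_des=fd,
            k=k,
            tracer_arrival_day=arr,
        )
        for lid, top, bot, rho, fa, fd, k, arr in DIMETHOMORPH_LAYERS
    ]


@pytest.fixture
def dimethomorph():
    return PesticideParams(
        name="dimethomorph", f_soil=0.2544, p_dp_soil=0.12, p_dp_foliar=0.02
    )


@pytest.fixture
def single_soil_dose():
    # typical field dose, 0.64 kg a.i./ha applied to the soil on day 0
    return [ApplicationEvent(day=0, route="soil", dose=0.64e6)]


@pytest.fixture
def two_layer_profile():
    return [
        SoilLayer("top", 0.0, 0.2, 0.5, 0.9, 0.05, 0.1, tracer_arrival_day=3),
        SoilLayer("sub", 0.2, 0.4, 0.6, 0.8, 0.02, 0.01, tracer_arrival_day=40),
    ]
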