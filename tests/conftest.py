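import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def spine_phantom():
    """The default spine phantom volume and its isocenter."""
    from stereodrr.fixtures import make_phantom, spine_phantom_spec

    return make_phantom(spine_phantom_spec())


@pytest.fixture(scope="session")
def dicom_phantom_dir(tmp_path_factory, spine_phantom):
    """Phantom written once as DICOM CT series + RT Plan + config."""
    from stereodrr.fixtures import make_synthetic_config, write_ct_series
    from stereodrr.projective import DetectorModel
    from stereodrr.stereo_geometry import RoomGeometry

    vol, iso = spine_phantom
    out = tmp_path_factory.mktemp("phantom")
    series_dir, rtplan = write_ct_series(vol, iso, out)
    config = make_synthetic_config(RoomGeometry(), DetectorModel.standard(),
                                   out / "config.ini")
    return {"root": out, "series": series_dir, "rtplan": rtplan,
            "config": config}


def random_room(rng):
    """A physically plausible random stereo room geometry."""
    from stereodrr.stereo_geometry import RoomGeometry

    sid = rng.uniform(1200.0, 2600.0)
    return RoomGeometry(
        sid=sid,
        sod=sid * rng.uniform(0.4, 0.8),
        theta=np.radians(rng.uniform(10.0, 80.0)),
        phi=np.radians(rng.uniform(20.0, 160.0)),
    )


def random_detector(rng):
    from stereodrr.projective import DetectorModel

    side = int(rng.choice([256, 512]))
    return DetectorModel(
        sx=rng.uniform(0.1, 1.0),
        sy=rng.uniform(0.1, 1.0),
        cx=rng.uniform(-300.0, 300.0),
        cy=rng.uniform(-300.0, 300.0),
        width=side, height=side, binning=2,
    )
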