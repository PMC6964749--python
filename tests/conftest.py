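import numpy as np
import pytest

from vmatqa.rtplan import Arc, ControlPoint, MLCGeometry, VMATPlan
from vmatqa.synthetic import CohortSpec, generate_anatomy, generate_plan


@pytest.fixture(scope="session")
def geometry():
    return MLCGeometry.default()


@pytest.fixture(scope="session")
def spec():
    return CohortSpec()


@pytest.fixture(scope="session")
def anatomy(spec):
    return generate_anatomy(spec, 1)


@pytest.fixture(scope="session")
def conformal_plan(anatomy, spec):
    return generate_plan(anatomy, 0.0, spec, 2, plan_id="conformal")


@pytest.fixture(scope="session")
def modulated_plan(anatomy, spec):
    return generate_plan(anatomy, 0.6, spec, 3, plan_id="modulated")


def tiny_geometry(n_pairs=3, width=10.0):
    half = n_pairs * width / 2
    return MLCGeometry(n_pairs, np.full(n_pairs, width),
                       -half + width * np.arange(n_pairs + 1))


def make_cp(gantry, weight, bank_a, bank_b, jaw_x=(-100.0, 100.0),
            jaw_y=(-100.0, 100.0)):
    return ControlPoint(gantry, weight, np.asarray(bank_a, float),
                        np.asarray(bank_b, float), jaw_x, jaw_y)


def make_plan(cps, beam_mu=400.0, geometry=None, rx=2.0, direction="CW"):
    geometry = geometry or tiny_geometry()
    return VMATPlan("test", [Arc(list(cps), beam_mu, direction)], rx, 38, geometry)
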