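"""Shared fixtures: tiny ensemble factory and random rigid motions."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from uturn.model_io import AtomTable, Ensemble

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture
def make_ens():
    """Factory: build an Ensemble from (resnum, resname, atom[, element])
    rows and a coordinate array of shape (n_frames, n_atoms, 3)."""

    def _make(atoms, coords, dt=None):
        nums = [a[0] for a in atoms]
        names = [a[1] for a in atoms]
        anames = [a[2] for a in atoms]
        elements = [a[3] for a in atoms] if len(atoms[0]) == 4 else None
        table = AtomTable(nums, names, anames, elements)
        coords = np.asarray(coords, dtype=float)
        if coords.ndim == 2:
            coords = coords[None]
        return Ensemble(table, coords, dt=dt)

    return _make


@pytest.fixture
def random_rigid():
    """Factory: seeded proper rotation + translation, applied frame-wise."""

    def _make(seed=0, translation_scale=20.0):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(3, 3))
        q, r = np.linalg.qr(a)
        q = q @ np.diag(np.sign(np.diag(r)))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        t = rng.normal(scale=translation_scale, size=3)

        def apply(ens: Ensemble) -> Ensemble:
            return ens.with_coords(ens.coords @ q.T + t)

        return q, t, apply

    return _make
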