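"""Shared fixtures: small synthetic populations and canonical masks."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from rosetteqtl.magicsim import simulate_founders, simulate_magic_population
from rosetteqtl.morphometry import RosetteMask
from rosetteqtl.rosette import RosetteSpec, generate_rosette_mask

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def disk_mask() -> RosetteMask:
    """Rasterized ideal disk, radius 20 mm at 0.05 mm/px (800 px diameter)."""
    mask, _ = generate_rosette_mask(
        RosetteSpec(n_leaves=0, center_radius_mm=20.0, image_size_px=1024, mm_per_px=0.05)
    )
    return mask


@pytest.fixture(scope="session")
def rectangle_mask() -> RosetteMask:
    """100 x 10 mm rectangle at 0.1 mm/px."""
    fg = np.zeros((1200, 1200), dtype=bool)
    fg[100:1100, 500:600] = True
    return RosetteMask(pixels=fg, mm_per_px=0.1)


@pytest.fixture(scope="session")
def star_rosette():
    """A reproducible 7-leaf rosette mask plus its vector geometry."""
    spec = RosetteSpec(
        n_leaves=7,
        blade_length_mm=18.0,
        blade_width_mm=5.0,
        petiole_length_mm=10.0,
        petiole_width_mm=1.5,
        center_radius_mm=4.5,
        image_size_px=1024,
        mm_per_px=0.08,
        seed=11,
    )
    mask, shape = generate_rosette_mask(spec)
    return spec, mask, shape


@pytest.fixture(scope="session")
def small_population():
    """19 founders, 2 x 50 markers, 150 lines — shared by scan tests."""
    panel = simulate_founders(19, (50, 50), seed=101)
    pop = simulate_magic_population(
        panel, 150, expected_breakpoints_per_chrom=3.0, error_rate=0.01, seed=102
    )
    return pop
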