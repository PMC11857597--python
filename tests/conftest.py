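"""Shared fixtures: layouts, rendered scenes, and small text fixtures."""

from __future__ import annotations

import numpy as np
import pytest

from microspot import (
    SyntheticSceneConfig,
    default_amplitudes,
    default_layout,
    render_synthetic_array,
)

#: Three sub-cutoff dust discs used across detection tests (x, y, radius, amp).
DUST = (((600.0, 600.0), 3.0, 180.0), ((150.0, 650.0), 3.0, 150.0), ((900.0, 150.0), 3.0, 160.0))


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def amplitudes(layout):
    return default_amplitudes(layout)


@pytest.fixture(scope="session")
def noiseless_scene(layout, amplitudes):
    config = SyntheticSceneConfig(
        layout=layout, amplitude_map=amplitudes, noise_sigma=0.0, seed=0
    )
    image, truth = render_synthetic_array(config)
    return config, image, truth


@pytest.fixture(scope="session")
def noisy_scene(layout, amplitudes):
    config = SyntheticSceneConfig(
        layout=layout, amplitude_map=amplitudes, noise_sigma=5.0, seed=11, artifacts=DUST
    )
    image, truth = render_synthetic_array(config)
    return config, image, truth


def write_gpr(path, rows, *, extra_header=("Type=GenePix Results 3",), wavelength=532):
    """Write a minimal valid ATF/GPR file for reader tests."""
    cols = ["Block", "Row", "Column", "Name", f"F{wavelength} Median", f"B{wavelength} Median"]
    lines = ["ATF\t1.0", f"{len(extra_header)}\t{len(cols)}"]
    lines += [f'"{h}"' for h in extra_header]
    lines.append("\t".join(f'"{c}"' for c in cols))
    for r in rows:
        lines.append("\t".join(str(v) for v in r))
    path.write_text("\n".join(lines) + "\n")
    return path
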