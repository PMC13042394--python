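import numpy as np
import pandas as pd
import pytest

import villustat as vs


def tiny_tissue(seed: int = 0, **overrides) -> vs.TissueConfig:
    """A desk-sized section: ~1,500 spots, 60 genes; fast enough to replicate."""
    base = dict(
        section_width_um=160.0,
        section_height_um=100.0,
        spot_pitch_um=2.0,
        n_villi=3,
        crypt_band_um=24.0,
        muscle_band_um=12.0,
        n_genes=60,
        seed=seed,
    )
    base.update(overrides)
    return vs.TissueConfig(**base)


@pytest.fixture(scope="session")
def small_section():
    cfg = tiny_tissue(seed=7)
    spots, counts, gt = vs.simulate_section(cfg)
    return cfg, spots, counts, gt


@pytest.fixture()
def toy_spots():
    """Hand-laid 4x3 grid: muscle row, crypt row, enterocyte/LP row."""
    rows = []
    comp = {0: "smooth_muscle", 2: "crypt", 4: "enterocyte"}
    i = 0
    for y in (1.0, 3.0, 5.0):
        for x in (1.0, 3.0, 5.0, 7.0):
            rows.append((f"s{i}", x, y, comp[int(y) - 1], ""))
            i += 1
    return pd.DataFrame(rows, columns=["spot_id", "x_um", "y_um",
                                       "compartment", "cell_type"])


def brute_force_nearest(query: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Independent exhaustive nearest-distance oracle."""
    out = np.empty(len(query))
    for i, q in enumerate(np.atleast_2d(query)):
        out[i] = np.sqrt(((np.atleast_2d(ref) - q) ** 2).sum(axis=1)).min()
    return out


def flood_fill_components(occ: np.ndarray, connectivity: int = 8) -> int:
    """Independent BFS flood-fill component counter on a boolean grid."""
    seen = np.zeros_like(occ, dtype=bool)
    if connectivity == 8:
        steps = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                 if (dy, dx) != (0, 0)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    n = 0
    h, w = occ.shape
    for sy in range(h):
        for sx in range(w):
            if occ[sy, sx] and not seen[sy, sx]:
                n += 1
                stack = [(sy, sx)]
                seen[sy, sx] = True
                while stack:
                    y, x = stack.pop()
                    for dy, dx in steps:
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and occ[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            stack.append((ny, nx))
    return n
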