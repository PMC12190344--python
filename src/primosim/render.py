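"""Snapshot rendering: agent scatter plots and lattice color images."""
from __future__ import annotations

import numpy as np

from .abm.params import ABMParams, AgentBreed
from .abm.state import ABMState

#: Breed colors of the agent view (WNTers green, FGFers yellow, Depositers red).
BREED_COLORS = {
    AgentBreed.WNTER: (0.2, 0.7, 0.2),
    AgentBreed.FGFER: (0.9, 0.8, 0.1),
    AgentBreed.DEPOSITER: (0.85, 0.2, 0.2),
}


def render_abm(
    state: ABMState,
    params: ABMParams,
    path: str,
    mode: str = "density",
) -> None:
    """Write a PNG of an agent-based model state.

    ``mode='breed'`` colors agents by breed; ``mode='density'`` shades agents
    red by neighbor count with the high-density ones highlighted cyan.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3))
    if mode == "breed":
        colors = [BREED_COLORS[AgentBreed(b)] for b in state.breed]
    elif mode == "density":
        top = max(int(state.neighbor_count.max()), 1)
        shade = 0.25 + 0.75 * state.neighbor_count / top
        colors = [
            (0.0, 0.9, 0.9) if f else (s, 0.08, 0.08)
            for f, s in zip(state.flagged_dense, shade)
        ]
    else:
        raise ValueError("mode must be 'breed' or 'density'")
    ax.scatter(state.pos[:, 0], state.pos[:, 1], c=colors, s=18)
    ax.set_aspect("equal")
    ax.set_title(f"step {state.step_index} ({mode} view)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def render_cpm(state, path: str) -> None:
    """Write a PNG of a lattice state using the published palette."""
    from .cpm.primordium import PALETTE

    import imageio.v3 as iio

    nt = len(state.types)
    lut = np.zeros((nt, 3), dtype=np.uint8)
    for i, t in enumerate(state.types):
        lut[i] = PALETTE.get(t.type_name, (128, 128, 128))
    type_of_pixel = state._type_idx_arr[state.lattice]
    img = lut[type_of_pixel]
    # darken cell boundaries for readability
    edge = np.zeros_like(state.lattice, dtype=bool)
    edge[:, :-1] |= state.lattice[:, :-1] != state.lattice[:, 1:]
    edge[:-1, :] |= state.lattice[:-1, :] != state.lattice[1:, :]
    img[edge] = (img[edge] * 0.55).astype(np.uint8)
    iio.imwrite(path, img[::-1])  # y up


def render_lattice_file(array_path: str, png_path: str) -> None:
    """Render a saved integer-lattice snapshot to a grayscale-coded PNG."""
    import imageio.v3 as iio

    lat = np.loadtxt(array_path, dtype=np.int64)
    ids = np.unique(lat)
    lut = np.zeros(ids.max() + 1, dtype=np.uint8)
    rng = np.random.default_rng(0)
    lut[ids] = rng.integers(40, 255, size=len(ids))
    lut[0] = 0
    iio.imwrite(png_path, lut[lat][::-1])
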