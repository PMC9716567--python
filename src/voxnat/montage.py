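"""32-channel 10-20 montage: positions and sensor neighborhoods."""

from __future__ import annotations

from functools import lru_cache

import numpy as np

#: recording montage: 32 Ag/AgCl electrodes of the international 10-20
#: system (AFz ground, left-earlobe online reference)
CHANNELS_32 = (
    "Fp1 Fp2 AF3 AF4 F7 F3 Fz F4 F8 FC5 FC1 FC2 FC6 T7 C3 Cz C4 T8 "
    "CP5 CP1 CP2 CP6 P7 P3 Pz P4 P8 PO7 PO3 PO4 PO8 Oz"
).split()

#: default neighbor threshold as a fraction of the head radius; gives
#: 4-6 neighbors per sensor on the template
NEIGHBOR_FRACTION = 0.7


@lru_cache(maxsize=4)
def channel_positions(ch_names: tuple = tuple(CHANNELS_32)) -> np.ndarray:
    """3-D template positions (meters, head frame) from the standard montage."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import mne

        montage = mne.channels.make_standard_montage("standard_1020")
    pos = montage.get_positions()["ch_pos"]
    return np.array([pos[c] for c in ch_names])


def neighbor_matrix(
    positions: np.ndarray | None = None,
    fraction: float = NEIGHBOR_FRACTION,
) -> np.ndarray:
    """Boolean sensor-adjacency matrix.

    Two sensors are neighbors when their distance is below
    ``fraction * head radius`` (head radius = mean distance of the
    sensors from the head origin).
    """
    if positions is None:
        positions = channel_positions()
    radius = float(np.linalg.norm(positions, axis=1).mean())
    d = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=2)
    nb = d < fraction * radius
    np.fill_diagonal(nb, False)
    return nb
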