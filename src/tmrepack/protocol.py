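"""Reference protocol arithmetic shipped as example configuration.

These are the small closed-form quantities of the docking / model-building
protocol: the docking search-box volume and the combinatorial count of
candidate homology models from a mainchain × sidechain sampling scheme.
"""

from __future__ import annotations

from .pocket_sites import SearchBox

#: example docking box (Å): full internal-cavity search volume, xy = membrane plane
EXAMPLE_DOCKING_BOX = SearchBox(
    center=(0.0, 0.0, 0.0),
    extents=(32.25, 26.25, 37.50),
)

#: search volume above which exhaustive docking needs a raised effort setting
LARGE_BOX_THRESHOLD_A3 = 30_000.0


def docking_box_volume(extents: tuple[float, float, float]) -> float:
    """Volume (Å³) of an axis-aligned docking box from its edge lengths."""
    return SearchBox(center=(0, 0, 0), extents=extents).volume


def candidate_model_count(n_mainchain: int, n_sidechain_per_mainchain: int) -> int:
    """Total candidate models when each mainchain model samples that many
    sidechain orientations."""
    if n_mainchain < 1 or n_sidechain_per_mainchain < 1:
        raise ValueError("counts must be ≥ 1")
    return n_mainchain * n_sidechain_per_mainchain
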