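"""Feature-extraction configuration."""

from __future__ import annotations

from dataclasses import dataclass, field

# (row, col) unit offsets for angles 0, 45, 90, 135 degrees
ANGLE_OFFSETS: dict[int, tuple[int, int]] = {
    0: (0, 1),
    45: (-1, 1),
    90: (-1, 0),
    135: (-1, -1),
}


@dataclass(frozen=True)
class FeatureConfig:
    """Knobs shared by the texture-matrix features.

    Parameters
    ----------
    discretization : ``"fixed_bin_width"`` or ``"fixed_bin_count"``.
        Fixed bin width (the radiomics default) keeps the level<->
        intensity relation comparable across lesions; fixed bin count
        fixes the matrix size instead.
    bin_value : bin width in intensity units, or number of bins.
    glcm_distance : co-occurrence offset length in pixels.
    angles : subset of {0, 45, 90, 135} degrees.
    aggregation : only ``"mean"`` (feature-wise mean over angles).
    gldm_alpha : maximum level difference for a neighbour to count as
        dependent.
    """

    discretization: str = "fixed_bin_width"
    bin_value: float = 25.0
    glcm_distance: int = 1
    angles: tuple[int, ...] = (0, 45, 90, 135)
    aggregation: str = "mean"
    normalize_matrices: bool = True
    gldm_alpha: int = 0

    def __post_init__(self) -> None:
        if self.discretization not in ("fixed_bin_width", "fixed_bin_count"):
            raise ValueError(f"unknown discretization {self.discretization!r}")
        if self.bin_value <= 0:
            raise ValueError("bin_value must be positive")
        if self.glcm_distance < 1:
            raise ValueError("glcm_distance must be >= 1")
        if not self.angles:
            raise ValueError("angles must be nonempty")
        for a in self.angles:
            if a not in ANGLE_OFFSETS:
                raise ValueError(f"unsupported angle {a}; use 0/45/90/135")
        if self.aggregation != "mean":
            raise ValueError("only 'mean' angle aggregation is supported")

    def offsets(self) -> list[tuple[int, int]]:
        d = self.glcm_distance
        return [(dr * d, dc * d) for dr, dc in
                (ANGLE_OFFSETS[a] for a in self.angles)]
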