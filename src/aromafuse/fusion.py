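"""Low-level fusion: concatenate the scaled modality blocks column-wise.

Each modality is autoscaled separately first (so neither block dominates),
the blocks are concatenated row-aligned, and the combined matrix is
autoscaled once more.  The second pass is near-identity but guarantees the
fused table is exactly standardized regardless of how the inputs were
prepared.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from aromafuse.preprocessing import ScalingRecord, autoscale


@dataclass
class FusedMatrix:
    """Fused feature table with block bookkeeping.

    ``block_boundary`` is the number of leading columns belonging to the
    e-nose block; the remaining columns are acoustic.  ``scaling`` holds
    the statistics of the final autoscale pass so either block can be
    recovered exactly.
    """

    data: pd.DataFrame
    block_boundary: int
    scaling: ScalingRecord

    @property
    def enose(self) -> pd.DataFrame:
        return self.data.iloc[:, : self.block_boundary]

    @property
    def acoustic(self) -> pd.DataFrame:
        return self.data.iloc[:, self.block_boundary:]

    def unscale(self) -> pd.DataFrame:
        """Undo the final autoscale pass, recovering the concatenated inputs."""
        return self.scaling.inverse_transform(self.data)


def fuse(enose_scaled: pd.DataFrame, acoustic_scaled: pd.DataFrame) -> FusedMatrix:
    """Column-wise concatenation [e-nose | acoustic] plus a final autoscale.

    Rows must be aligned: equal length and, when both carry a meaningful
    index, identical indices.  Row order and count are never changed.
    A zero-width block is allowed (single-modality arm).
    """
    if len(enose_scaled) and len(acoustic_scaled):
        if len(enose_scaled) != len(acoustic_scaled):
            raise ValueError(
                f"row-count mismatch: e-nose {len(enose_scaled)} vs "
                f"acoustic {len(acoustic_scaled)}"
            )
        if not enose_scaled.index.equals(acoustic_scaled.index):
            raise ValueError("row keys of the two blocks do not align")
    overlap = set(enose_scaled.columns) & set(acoustic_scaled.columns)
    if overlap:
        raise ValueError(f"duplicate feature names across blocks: {sorted(overlap)}")
    if acoustic_scaled.shape[1] == 0:
        combined = enose_scaled.copy()
    elif enose_scaled.shape[1] == 0:
        combined = acoustic_scaled.copy()
    else:
        combined = pd.concat([enose_scaled, acoustic_scaled], axis=1)
    scaled, record = autoscale(combined, block="fused")
    boundary = sum(c in scaled.columns for c in enose_scaled.columns)
    return FusedMatrix(data=scaled, block_boundary=boundary, scaling=record)
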