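"""Expression/protein matrix container with sample annotations."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

TISSUES = ("BM", "MPB", "UCB")
PHASES = ("G0", "G1")


@dataclass
class ExpressionMatrix:
    """A features x samples intensity table plus a sample sheet.

    ``values``: DataFrame indexed by feature id, columns are sample ids,
    entries are positive intensities in arbitrary fluorescence (or LC/MS)
    units.  ``samples``: DataFrame indexed by sample id with columns
    ``tissue`` (BM/MPB/UCB), ``phase`` (G0/G1) and ``replicate``.
    ``feature_meta`` optionally carries per-feature metadata (e.g. protein
    priority ranks, gene-id cross-references).
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    feature_meta: pd.DataFrame | None = field(default=None)

    def validate(self) -> "ExpressionMatrix":
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate feature id: {dup!r}")
        if list(self.values.columns) != list(self.samples.index):
            missing = set(self.values.columns) ^ set(self.samples.index)
            raise ValueError(
                f"sample sheet does not match matrix columns (mismatch: {sorted(missing)})"
            )
        bad = self.values.le(0)
        if bad.any().any():
            col = bad.any(axis=0).idxmax() if bad.any().any() else None
            feat = bad[bad.any(axis=1)].index[0]
            samp = bad.loc[feat][bad.loc[feat]].index[0]
            raise ValueError(
                f"nonpositive intensity for feature {feat!r} in sample {samp!r}"
            )
        for col, allowed in (("tissue", TISSUES), ("phase", PHASES)):
            vals = set(self.samples[col])
            if not vals <= set(allowed):
                raise ValueError(f"invalid {col} values: {sorted(vals - set(allowed))}")
        counts = self.samples.groupby(["tissue", "phase"]).size()
        low = counts[counts < 2]
        if not low.empty:
            raise ValueError(f"fewer than 2 replicates in group(s): {list(low.index)}")
        return self

    def group_columns(self, tissue: str, phase: str) -> list[str]:
        mask = (self.samples["tissue"] == tissue) & (self.samples["phase"] == phase)
        return list(self.samples.index[mask])

    @property
    def n_features(self) -> int:
        return self.values.shape[0]
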