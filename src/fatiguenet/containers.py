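"""Shared in-memory containers for cohort-level tabular data."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BLOCKS = ("symptom", "index")


@dataclass(frozen=True)
class Feature:
    """One symptom or clinical index in the feature catalog.

    ``code`` is the short identifier used in tables and networks (e.g. ``TC1``
    for white tongue coating, ``SBP`` for systolic blood pressure), ``block``
    says whether the feature is a TCM symptom/sign or a Western-medicine
    index, and ``prevalence`` is the baseline probability of the feature
    being positive in the absence of any latent factor.
    """

    code: str
    label: str
    block: str
    prevalence: float = 0.0

    def __post_init__(self) -> None:
        if self.block not in BLOCKS:
            raise ValueError(f"block must be one of {BLOCKS}, got {self.block!r}")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(f"prevalence must be in [0, 1], got {self.prevalence}")


@dataclass
class BinaryCohortMatrix:
    """Subjects x features 0/1 matrix plus the feature catalog.

    ``data`` rows are subjects (index = subject id), columns are feature
    codes in catalog order.
    """

    data: pd.DataFrame
    features: list[Feature]

    def __post_init__(self) -> None:
        codes = [f.code for f in self.features]
        if list(self.data.columns) != codes:
            raise ValueError("matrix columns must match the feature catalog codes, in order")
        values = self.data.to_numpy()
        if values.size and not np.isin(values, (0, 1)).all():
            raise ValueError("cohort matrix must be binary (0/1)")

    @property
    def codes(self) -> list[str]:
        return [f.code for f in self.features]

    def block_of(self, code: str) -> str:
        for f in self.features:
            if f.code == code:
                return f.block
        raise KeyError(code)

    def subset(self, blocks: tuple[str, ...] | None = None) -> "BinaryCohortMatrix":
        """Restrict to features of the given blocks (None keeps everything)."""
        if blocks is None:
            return self
        feats = [f for f in self.features if f.block in blocks]
        return BinaryCohortMatrix(self.data[[f.code for f in feats]], feats)


@dataclass
class TonguePulseTable:
    """Per-subject continuous tongue-colour and pulse-sphygmogram parameters.

    ``tongue_cols`` / ``pulse_cols`` name the columns belonging to each
    block; a table may carry additional bookkeeping columns (e.g. group)
    outside the two blocks.
    """

    data: pd.DataFrame
    tongue_cols: list[str] = field(default_factory=list)
    pulse_cols: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in self.tongue_cols + self.pulse_cols if c not in self.data.columns]
        if missing:
            raise ValueError(f"columns declared but absent from table: {missing}")

    @property
    def tongue(self) -> pd.DataFrame:
        return self.data[self.tongue_cols]

    @property
    def pulse(self) -> pd.DataFrame:
        return self.data[self.pulse_cols]
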