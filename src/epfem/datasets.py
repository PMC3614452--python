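"""Current-voltage datasets: the input of the inverse analysis."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd


@dataclass
class IVDataset:
    """Measured or synthetic (U_j, I_j) pairs.

    ``U`` in volts, ``I`` in amperes; replicate voltages are allowed (each
    measurement contributes its own residual to the inverse objective).
    ``provenance`` records how the data were produced (for synthetic data:
    the ground-truth parameters, noise level and seed) and is written to a
    JSON sidecar next to the CSV; the fitting code never reads it.
    """

    U: np.ndarray
    I: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.U = np.asarray(self.U, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.U.shape != self.I.shape or self.U.ndim != 1:
            raise ValueError("U and I must be equal-length 1-D arrays")
        if np.any(self.U <= 0) or np.any(self.I <= 0):
            raise ValueError("U and I must be positive")

    @property
    def n(self) -> int:
        return len(self.U)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"U_V": self.U, "I_A": self.I})

    def to_csv(self, path, sidecar: bool = True) -> None:
        self.to_dataframe().to_csv(path, index=False)
        if sidecar and self.provenance:
            with open(str(path) + ".json", "w") as fh:
                json.dump(self.provenance, fh, indent=2, sort_keys=True)

    @classmethod
    def from_csv(cls, path, provenance: Optional[dict] = None) -> "IVDataset":
        df = pd.read_csv(path)
        return cls(
            U=df["U_V"].to_numpy(), I=df["I_A"].to_numpy(),
            provenance=provenance or {},
        )
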