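"""Right-censored competing-risks survival data.

One row per subject: positive follow-up time, integer status code
(0 = censored, k = event of cause k for k = 1..K) and covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SurvivalDataset"]

RESERVED = ("id", "time", "status")


@dataclass
class SurvivalDataset:
    """Competing-risks dataset backed by a pandas DataFrame.

    Parameters
    ----------
    frame
        Must contain columns ``time`` and ``status``; ``id`` is added
        (0..n-1) if absent.  Every other column is a covariate.
    n_causes
        Number of competing causes K.  Inferred as ``max(status)`` when
        not given.
    """

    frame: pd.DataFrame
    n_causes: int | None = None

    def __post_init__(self) -> None:
        df = self.frame
        for col in ("time", "status"):
            if col not in df.columns:
                raise ValueError(f"dataset is missing required column {col!r}")
        if "id" not in df.columns:
            df = df.copy()
            df.insert(0, "id", np.arange(len(df)))
        if len(df) == 0:
            raise ValueError("dataset is empty")
        time = df["time"].to_numpy(dtype=float)
        status = df["status"].to_numpy()
        bad = np.flatnonzero(~(time > 0))
        if bad.size:
            raise ValueError(f"nonpositive time at rows {bad[:10].tolist()}")
        if not np.all(status == status.astype(int)):
            raise ValueError("status codes must be integers")
        status = status.astype(int)
        if self.n_causes is None:
            self.n_causes = max(int(status.max()), 1)
        bad = np.flatnonzero((status < 0) | (status > self.n_causes))
        if bad.size:
            raise ValueError(
                f"status outside 0..{self.n_causes} at rows {bad[:10].tolist()}"
            )
        cov = [c for c in df.columns if c not in RESERVED]
        if df[cov].isna().any().any():
            raise ValueError("missing covariate values are not allowed")
        self.frame = df

    # -- accessors -------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def time(self) -> np.ndarray:
        return self.frame["time"].to_numpy(dtype=float)

    @property
    def status(self) -> np.ndarray:
        return self.frame["status"].to_numpy(dtype=int)

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.frame.columns if c not in RESERVED]

    def covariates(self, names: list[str] | None = None) -> pd.DataFrame:
        return self.frame[names if names is not None else self.covariate_names]

    def events(self, cause: int | None = None) -> int:
        """Number of events of ``cause`` (any cause when None)."""
        if cause is None:
            return int((self.status > 0).sum())
        return int((self.status == cause).sum())

    def causes(self) -> range:
        return range(1, self.n_causes + 1)
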