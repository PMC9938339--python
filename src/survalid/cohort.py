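"""Subject-level cohort container.

A cohort is a table of subjects with follow-up time (years), an event code
(0 = censored, 1 = outcome event, 2 = competing non-outcome death), age, and
an arbitrary set of named covariates. Missing covariate values are NaN.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RESERVED_COLUMNS = ("id", "time", "event", "age")

EVENT_CENSORED = 0
EVENT_OUTCOME = 1
EVENT_COMPETING = 2


class Cohort:
    """A validated subject table.

    Parameters
    ----------
    df : pandas.DataFrame
        Must contain columns ``id``, ``time``, ``event`` and ``age``. Any
        remaining columns are treated as covariates. ``time`` must be
        strictly positive and ``event`` must take values in {0, 1, 2}.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        missing = [c for c in RESERVED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"cohort table lacks required columns: {missing}")
        df["time"] = pd.to_numeric(df["time"])
        df["event"] = pd.to_numeric(df["event"]).astype(int)
        df["age"] = pd.to_numeric(df["age"])
        if (df["time"] <= 0).any():
            bad = df.loc[df["time"] <= 0, "id"].tolist()[:5]
            raise ValueError(f"follow-up times must be > 0 (offending ids: {bad})")
        if not df["event"].isin([EVENT_CENSORED, EVENT_OUTCOME, EVENT_COMPETING]).all():
            bad = sorted(set(df["event"]) - {0, 1, 2})
            raise ValueError(f"event codes must be in {{0,1,2}}; found {bad}")
        self.df = df.reset_index(drop=True)

    # -- basic accessors ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def times(self) -> np.ndarray:
        return self.df["time"].to_numpy(dtype=float)

    @property
    def events(self) -> np.ndarray:
        """Event codes, 0/1/2."""
        return self.df["event"].to_numpy(dtype=int)

    @property
    def ages(self) -> np.ndarray:
        return self.df["age"].to_numpy(dtype=float)

    @property
    def ids(self) -> np.ndarray:
        return self.df["id"].to_numpy()

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.df.columns if c not in RESERVED_COLUMNS]

    def covariates(self) -> pd.DataFrame:
        """Covariate columns only (age is also exposed as a covariate)."""
        cov = self.df[self.covariate_names].copy()
        cov.insert(0, "age", self.df["age"])
        return cov

    def n_events(self, code: int = EVENT_OUTCOME) -> int:
        return int((self.df["event"] == code).sum())

    def subset(self, mask: Iterable[bool]) -> "Cohort":
        mask = np.asarray(list(mask), dtype=bool)
        return Cohort(self.df.loc[mask])

    # -- transformations ---------------------------------------------------
    def cap_horizon(self, horizon: float) -> "Cohort":
        """Administratively censor follow-up at ``horizon`` years.

        Subjects with time beyond the horizon have their time set to the
        horizon and their event code set to censored, matching a validation
        limited to a fixed prediction horizon.
        """
        df = self.df.copy()
        over = df["time"] > horizon
        n_over = int(over.sum())
        if n_over:
            logger.info("horizon capping: %d subjects censored at %.3g years", n_over, horizon)
        df.loc[over, "event"] = EVENT_CENSORED
        df.loc[over, "time"] = horizon
        return Cohort(df)

    # -- IO ----------------------------------------------------------------
    @classmethod
    def from_csv(cls, path) -> "Cohort":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"Cohort(n={len(self)}, events={self.n_events(1)}, "
            f"competing={self.n_events(2)})"
        )
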