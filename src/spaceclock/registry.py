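"""Registry of epigenetic clocks: names, functional categories, and units.

A clock registry declares which clocks a dataset is expected to carry, which
functional category each belongs to (chronological-age predictors, mortality
predictors, organ-system clocks, ...) and whether the clock reports an age in
years or a unitless pace of aging.  Only year-scale clocks enter cross-clock
averaging and significance testing; pace clocks (DunedinPACE) are analysed on
their own scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

#: Recognised functional categories.
CATEGORIES = (
    "chronological",
    "mortality",
    "fitness",
    "causal",
    "intrinsic",
    "stochastic",
    "retroelement",
    "organ",
    "pace",
)

YEAR_UNITS = "years"
RATE_UNITS = "rate"

#: The 12-cell immune panel used for methylation deconvolution
#: (Salas-style extended leukocyte panel).
CELL_TYPES = (
    "Bas",
    "Bnv",
    "Bmem",
    "CD4nv",
    "CD4mem",
    "CD8nv",
    "CD8mem",
    "Treg",
    "NK",
    "Mono",
    "Neu",
    "Eos",
)


@dataclass(frozen=True)
class ClockInfo:
    """One registered clock."""

    name: str
    category: str
    units: str = YEAR_UNITS


class ClockRegistry:
    """Immutable collection of :class:`ClockInfo` with unique names.

    Invariants enforced on construction: names unique, categories recognised,
    and ``category == "pace"`` if and only if ``units == "rate"``.
    """

    def __init__(self, clocks: Iterable[ClockInfo]):
        clocks = list(clocks)
        names = [c.name for c in clocks]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate clock names in registry: {dup}")
        for c in clocks:
            if c.category not in CATEGORIES:
                raise ValueError(
                    f"unknown category {c.category!r} for clock {c.name!r}; "
                    f"expected one of {CATEGORIES}"
                )
            if (c.category == "pace") != (c.units == RATE_UNITS):
                raise ValueError(
                    f"clock {c.name!r}: category 'pace' must pair with units "
                    f"'rate' (got category={c.category!r}, units={c.units!r})"
                )
        self._clocks: dict[str, ClockInfo] = {c.name: c for c in clocks}

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._clocks)

    def __iter__(self) -> Iterator[ClockInfo]:
        return iter(self._clocks.values())

    def __contains__(self, name: object) -> bool:
        return name in self._clocks

    # -- accessors ----------------------------------------------------------
    @property
    def names(self) -> list[str]:
        return list(self._clocks)

    @property
    def year_clocks(self) -> list[str]:
        """Clocks expressed in years — the set used for averaging/testing."""
        return [c.name for c in self if c.units == YEAR_UNITS]

    @property
    def pace_clocks(self) -> list[str]:
        return [c.name for c in self if c.units == RATE_UNITS]

    def category_of(self, name: str) -> str:
        return self._require(name).category

    def units_of(self, name: str) -> str:
        return self._require(name).units

    def _require(self, name: str) -> ClockInfo:
        try:
            return self._clocks[name]
        except KeyError:
            raise KeyError(f"clock {name!r} is not registered") from None

    # -- (de)serialisation --------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c.name, c.category, c.units) for c in self],
            columns=["clock", "category", "units"],
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ClockRegistry":
        required = {"clock", "category", "units"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"registry table missing columns: {sorted(missing)}")
        return cls(
            ClockInfo(str(r.clock), str(r.category), str(r.units))
            for r in frame.itertuples()
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ClockRegistry":
        return cls.from_frame(pd.read_csv(path))


#: Default clock inventory: 31 year-scale clocks in nine categories plus the
#: DunedinPACE pace-of-aging estimator.
_DEFAULT_CLOCK_LIST: tuple[tuple[str, str], ...] = (
    ("Horvath", "chronological"),
    ("Hannum", "chronological"),
    ("PCHorvath1", "chronological"),
    ("PCHorvath2", "chronological"),
    ("PCHannum", "chronological"),
    ("PhenoAge", "mortality"),
    ("OMICmAge", "mortality"),
    ("PCPhenoAge", "mortality"),
    ("PCGrimAge", "mortality"),
    ("DNAmFitAge", "fitness"),
    ("AdaptAge", "causal"),
    ("CausAge", "causal"),
    ("DamAge", "causal"),
    ("IntrinClock", "intrinsic"),
    ("Stochastic.Zhang", "stochastic"),
    ("Stochastic.Horvath", "stochastic"),
    ("Stochastic.PhenoAge", "stochastic"),
    ("Retroclock", "retroelement"),
    ("Retroclockv2", "retroelement"),
    ("SystemsAge", "organ"),
    ("Blood", "organ"),
    ("Brain", "organ"),
    ("Inflammation", "organ"),
    ("Heart", "organ"),
    ("Hormone", "organ"),
    ("Immune", "organ"),
    ("Kidney", "organ"),
    ("Liver", "organ"),
    ("Metabolic", "organ"),
    ("Lung", "organ"),
    ("MusculoSkeletal", "organ"),
)


def default_registry() -> ClockRegistry:
    """The 31 year-scale clocks (nine categories) plus DunedinPACE."""
    clocks = [ClockInfo(name, cat, YEAR_UNITS) for name, cat in _DEFAULT_CLOCK_LIST]
    clocks.append(ClockInfo("DunedinPACE", "pace", RATE_UNITS))
    return ClockRegistry(clocks)
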