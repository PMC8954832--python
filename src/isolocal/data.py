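"""Core data model and I/O for lamb stable-isotope libraries.

A *library* is an ordered table of lamb samples, each carrying four stable
isotope ratios expressed in delta notation (per mil): d13C vs V-PDB, d15N vs
Air, d2H and d18O vs SMOW.  Samples come from four banners (counties) of
Inner Mongolia; the two Sunite banners constitute the PGI (Protected
Geographical Indication) region, the other two are the non-PGI class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BANNERS",
    "PGI_BANNERS",
    "ISOTOPES",
    "PGI",
    "NON_PGI",
    "IsotopeRecord",
    "IsotopeLibrary",
    "SplitResult",
    "ParseError",
    "read_library",
    "write_library",
    "stratified_split",
    "write_split",
    "delta_permil",
]

#: Banner (county) identifiers, in the order the study lists them.
BANNERS = ("SuniteRight", "SuniteLeft", "Siziwang", "Abaga")
#: Banners inside the protected (PGI) region.
PGI_BANNERS = frozenset({"SuniteRight", "SuniteLeft"})
#: Isotope column names, fixed on-disk order.
ISOTOPES = ("d13C", "d15N", "d2H", "d18O")

PGI = "PGI"
NON_PGI = "nonPGI"

_REQUIRED_COLUMNS = ("sample_id", "banner") + ISOTOPES


class ParseError(ValueError):
    """Raised when a library file violates the expected schema."""


def group_for_banner(banner: str) -> str:
    """Class label implied by a banner: Sunite banners are PGI."""
    if banner not in BANNERS:
        raise ParseError(f"unknown banner {banner!r}; expected one of {BANNERS}")
    return PGI if banner in PGI_BANNERS else NON_PGI


@dataclass(frozen=True)
class IsotopeRecord:
    """One lamb sample: identifiers, provenance and the four delta values (per mil)."""

    sample_id: str
    banner: str
    d13C: float
    d15N: float
    d2H: float
    d18O: float
    group: str = ""

    def __post_init__(self) -> None:
        if self.banner not in BANNERS:
            raise ParseError(
                f"unknown banner {self.banner!r} for sample {self.sample_id!r}"
            )
        expected = group_for_banner(self.banner)
        if self.group == "":
            object.__setattr__(self, "group", expected)
        elif self.group != expected:
            raise ParseError(
                f"sample {self.sample_id!r}: group {self.group!r} inconsistent "
                f"with banner {self.banner!r} (expected {expected!r})"
            )
        for name in ISOTOPES:
            value = getattr(self, name)
            if not np.isfinite(value):
                raise ParseError(
                    f"sample {self.sample_id!r}: non-finite {name} value {value!r}"
                )

    @property
    def values(self) -> np.ndarray:
        """The four delta values as a float vector (d13C, d15N, d2H, d18O)."""
        return np.array([self.d13C, self.d15N, self.d2H, self.d18O], dtype=float)


@dataclass
class IsotopeLibrary:
    """An ordered collection of :class:`IsotopeRecord` with unique sample ids."""

    records: list[IsotopeRecord]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("a library must contain at least one record")
        ids = [r.sample_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[IsotopeRecord]:
        return iter(self.records)

    def __getitem__(self, idx: int) -> IsotopeRecord:
        return self.records[idx]

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    @property
    def groups(self) -> list[str]:
        return [r.group for r in self.records]

    @property
    def banners(self) -> list[str]:
        return [r.banner for r in self.records]

    @property
    def values(self) -> np.ndarray:
        """n x 4 matrix of delta values in the fixed isotope order."""
        return np.array([r.values for r in self.records], dtype=float)

    def subset(self, indices: Sequence[int], label: str | None = None) -> "IsotopeLibrary":
        """A new library holding ``records[i]`` for each index, in the given order."""
        return IsotopeLibrary(
            [self.records[i] for i in indices],
            label=self.label if label is None else label,
        )

    def sorted_by_id(self) -> "IsotopeLibrary":
        """Canonical ordering by sample_id; used before any order-sensitive step."""
        order = sorted(range(len(self)), key=lambda i: self.records[i].sample_id)
        return self.subset(order)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "banner": self.banners,
                "group": self.groups,
                **{iso: [getattr(r, iso) for r in self.records] for iso in ISOTOPES},
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, label: str = "") -> "IsotopeLibrary":
        missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise ParseError(f"missing required column(s): {', '.join(missing)}")
        records = []
        for pos, row in enumerate(frame.itertuples(index=False)):
            raw = row._asdict()
            deltas = {}
            for iso in ISOTOPES:
                try:
                    deltas[iso] = float(raw[iso])
                except (TypeError, ValueError) as exc:
                    raise ParseError(
                        f"row {pos}: non-numeric {iso} value {raw[iso]!r}"
                    ) from exc
            group = str(raw.get("group", "") or "")
            try:
                records.append(
                    IsotopeRecord(
                        sample_id=str(raw["sample_id"]),
                        banner=str(raw["banner"]),
                        group=group,
                        **deltas,
                    )
                )
            except ParseError as exc:
                raise ParseError(f"row {pos}: {exc}") from exc
        return cls(records, label=label)


def read_library(path: str | Path, delimiter: str = ",", label: str = "") -> IsotopeLibrary:
    """Read a library from delimited text (CSV by default).

    The header must contain ``sample_id, banner, d13C, d15N, d2H, d18O``;
    a ``group`` column is optional and, when absent, is derived from the
    banner.  Schema violations raise :class:`ParseError` naming the column
    or row at fault.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, delimiter=delimiter, dtype=str)
    if not label:
        label = path.stem
    return IsotopeLibrary.from_frame(frame, label=label)


def write_library(lib: IsotopeLibrary, path: str | Path, delimiter: str = ",") -> None:
    """Write a library as delimited text with the fixed column order."""
    lib.to_frame().to_csv(path, sep=delimiter, index=False)


@dataclass
class SplitResult:
    """A train/test partition of a library, reproducible from its seed."""

    training: IsotopeLibrary
    testing: IsotopeLibrary
    seed: int
    test_fraction: float

    def __post_init__(self) -> None:
        train_ids = set(self.training.sample_ids)
        test_ids = set(self.testing.sample_ids)
        if train_ids & test_ids:
            raise ValueError("training and testing sets overlap")


def _stratum_test_counts(counts: dict[str, int], test_fraction: float) -> dict[str, int]:
    """Largest-remainder apportionment of the global test count over banners.

    Each banner's quota is ``n_banner * test_fraction``; banners start at the
    floor of their quota and the remaining seats (so that the total equals
    ``round(N * test_fraction)``) go to the largest fractional remainders,
    ties broken by banner order.
    """
    total = sum(counts.values())
    target = int(round(total * test_fraction))
    quotas = {b: n * test_fraction for b, n in counts.items()}
    alloc = {b: int(np.floor(q)) for b, q in quotas.items()}
    # Keep at least one training sample per banner.
    for b, n in counts.items():
        alloc[b] = min(alloc[b], n - 1)
    remaining = target - sum(alloc.values())
    order = sorted(
        counts, key=lambda b: (-(quotas[b] - np.floor(quotas[b])), list(counts).index(b))
    )
    i = 0
    while remaining > 0 and i < len(order):
        b = order[i]
        if alloc[b] < counts[b] - 1:
            alloc[b] += 1
            remaining -= 1
        i += 1
    while remaining < 0:
        # Over-allocation can only come from the per-banner rounding; trim the
        # smallest remainders first.
        for b in reversed(order):
            if alloc[b] > 0:
                alloc[b] -= 1
                remaining += 1
                break
    return alloc


def stratified_split(
    lib: IsotopeLibrary, test_fraction: float = 0.2, seed: int = 0
) -> SplitResult:
    """Stratified random train/test split, one stratum per banner.

    Within each banner ``round(n_banner * test_fraction)`` samples go to the
    test set, with a largest-remainder adjustment so the global test count
    equals ``round(N * test_fraction)`` exactly (a 4:1 split at the default
    fraction).  Deterministic given ``seed``.
    """
    if not 0 < test_fraction < 1:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    counts: dict[str, int] = {}
    for b in lib.banners:
        counts[b] = counts.get(b, 0) + 1
    for b, n in counts.items():
        if n < 2:
            raise ValueError(f"banner {b!r} has only {n} sample(s); cannot stratify")
    test_counts = _stratum_test_counts(counts, test_fraction)
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for b in counts:
        members = [i for i, rec in enumerate(lib.records) if rec.banner == b]
        chosen = rng.choice(len(members), size=test_counts[b], replace=False)
        test_idx.extend(members[i] for i in chosen)
    test_set = set(test_idx)
    train_idx = [i for i in range(len(lib)) if i not in test_set]
    return SplitResult(
        training=lib.subset(train_idx, label=f"{lib.label}-train"),
        testing=lib.subset(sorted(test_set), label=f"{lib.label}-test"),
        seed=seed,
        test_fraction=test_fraction,
    )


def write_split(split: SplitResult, prefix: str | Path) -> None:
    """Serialize a split as two CSVs plus a JSON sidecar with the seed."""
    prefix = Path(prefix)
    write_library(split.training, prefix.with_suffix(".train.csv"))
    write_library(split.testing, prefix.with_suffix(".test.csv"))
    sidecar = {
        "seed": split.seed,
        "test_fraction": split.test_fraction,
        "n_training": len(split.training),
        "n_testing": len(split.testing),
    }
    prefix.with_suffix(".split.json").write_text(json.dumps(sidecar, indent=2))


def delta_permil(
    r_sample: float, r_standard: float, convention: str = "conventional"
) -> float:
    """Delta notation (per mil) for an isotope ratio against a reference.

    ``conventional`` is the universal definition,
    ``(R_sample - R_standard) / R_standard * 1000``.  ``as_printed`` divides
    by ``R_sample`` instead, matching the formula some reports print; the two
    agree to first order for small deltas.
    """
    if r_sample <= 0 or r_standard <= 0:
        raise ValueError("isotope ratios must be positive")
    diff = r_sample - r_standard
    if convention == "conventional":
        return diff / r_standard * 1000.0
    if convention == "as_printed":
        return diff / r_sample * 1000.0
    raise ValueError(f"unknown convention {convention!r}")
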