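"""Synthetic dictation-time datasets with known ground truth.

Durations are drawn from a four-component structure mirroring how
timestamp-derived reading times actually arise:

* ``short``   — interrupt-truncated entries: Exponential(short_scale)
  truncated to (0, normal_mu);
* ``normal``  — true reading time: Normal(normal_mu, normal_sigma),
  resampled until positive;
* ``long``    — paused-and-resumed reports: a normal draw plus a shifted
  exponential continuation delay (e.g., overnight);
* ``unknown`` — Uniform over ``unknown_range``.

Generated durations are quantized to the microsecond grid so that a
round trip through a timestamp CSV reproduces them bit-exactly.  The
timestamp emitter can additionally inject rows whose first save precedes
the dictation start, to exercise the exclusion rule downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import DEFAULT_COLUMNS

__all__ = [
    "COMPONENTS",
    "GeneratorConfig",
    "LabeledDataset",
    "generate_durations",
    "to_timestamp_table",
    "write_dataset",
]

COMPONENTS = ("short", "normal", "long", "unknown")

#: Region -> representative RIS protocol code (resolves under the default
#: RegionMap patterns).
DEFAULT_REGION_CODES = {
    "head": "CT HEAD",
    "chest": "CT CHEST",
    "abdomen": "CT ABDOMEN",
    "foot": "CT FOOT",
    "lumbar_spine": "CT LUMBAR SPINE",
    "shoulder": "CT SHOULDER",
    "wrist": "CT WRIST",
    "polytrauma": "CT POLYTRAUMA",
    "other": "CT MISC",
}

_NS_PER_MIN = 6.0e10
_US_PER_MIN = 60_000_000


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground-truth parameters of one synthetic dataset."""

    n: int
    seed: int = 0
    weights: tuple[float, float, float, float] = (0.05, 0.85, 0.07, 0.03)
    normal_mu: float = 16.0
    normal_sigma: float = 5.0
    short_scale: float = 2.0
    long_shift: float = 300.0
    long_scale: float = 200.0
    unknown_range: tuple[float, float] = (0.2, 480.0)
    negative_save_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        w = np.asarray(self.weights, dtype=float)
        if w.size != 4 or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be 4 non-negative values summing to 1")
        if min(self.normal_sigma, self.short_scale, self.long_scale) <= 0:
            raise ValueError("scales must be positive")
        if self.normal_mu <= 0:
            raise ValueError("normal_mu must be positive")
        if self.long_shift < 0:
            raise ValueError("long_shift must be non-negative")
        lo, hi = self.unknown_range
        if not (hi > lo >= 0):
            raise ValueError("unknown_range must satisfy 0 <= low < high")
        if not 0.0 <= self.negative_save_rate < 1.0:
            raise ValueError("negative_save_rate must lie in [0, 1)")


@dataclass(frozen=True)
class LabeledDataset:
    """Durations (minutes) with ground-truth component labels."""

    durations: np.ndarray
    labels: np.ndarray
    config: GeneratorConfig

    def __post_init__(self) -> None:
        if len(self.durations) != len(self.labels):
            raise ValueError("durations and labels must have equal length")

    @property
    def n(self) -> int:
        return int(self.durations.size)


def _positive_normal(rng: np.random.Generator, mu: float, sigma: float, size: int) -> np.ndarray:
    """Normal draws resampled until strictly positive."""
    out = rng.normal(mu, sigma, size)
    bad = out <= 0.0
    while bad.any():
        out[bad] = rng.normal(mu, sigma, int(bad.sum()))
        bad = out <= 0.0
    return out


def generate_durations(config: GeneratorConfig) -> LabeledDataset:
    """Draw a labelled dataset from the four-component structure.

    Byte-identical for identical configs (single seed drives every draw;
    components are filled in a fixed order).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    comp = rng.choice(4, size=n, p=list(config.weights)) if n else np.empty(0, dtype=int)
    d = np.zeros(n, dtype=float)

    m_short = comp == 0
    k = int(m_short.sum())
    if k:
        # inverse-CDF sampling of Exponential(short_scale) truncated to (0, mu)
        cap = 1.0 - np.exp(-config.normal_mu / config.short_scale)
        u = rng.uniform(size=k)
        d[m_short] = -config.short_scale * np.log1p(-u * cap)

    m_normal = comp == 1
    k = int(m_normal.sum())
    if k:
        d[m_normal] = _positive_normal(rng, config.normal_mu, config.normal_sigma, k)

    m_long = comp == 2
    k = int(m_long.sum())
    if k:
        d[m_long] = (
            _positive_normal(rng, config.normal_mu, config.normal_sigma, k)
            + config.long_shift
            + rng.exponential(config.long_scale, k)
        )

    m_unknown = comp == 3
    k = int(m_unknown.sum())
    if k:
        lo, hi = config.unknown_range
        u = rng.uniform(lo, hi, k)
        bad = u <= 0.0
        while bad.any():
            u[bad] = rng.uniform(lo, hi, int(bad.sum()))
            bad = u <= 0.0
        d[m_unknown] = u

    # quantize to the microsecond grid via the same integer-ns arithmetic the
    # timestamp reader uses, so CSV round trips are bit-exact
    micro = np.maximum(np.round(d * _US_PER_MIN).astype(np.int64), 1)
    d = micro * 1000.0 / _NS_PER_MIN

    labels = np.array(COMPONENTS, dtype=object)[comp] if n else np.empty(0, dtype=object)
    return LabeledDataset(durations=d, labels=labels, config=config)


def to_timestamp_table(
    dataset: LabeledDataset,
    start_epoch: str | pd.Timestamp = "2020-01-06 08:00:00",
    region: str = "head",
    region_code: str | None = None,
    exams_per_day: int = 60,
    slot_minutes: int = 8,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit a timestamp table (and a truth-label table) for the dataset.

    Dictation starts are laid out over a business-day calendar;
    ``first_save = start + duration``.  A Binomial(n, negative_save_rate)
    number of extra rows with the save *before* the start is appended
    (labelled ``negative_save`` in the truth table) so the exclusion rule
    downstream has something to remove.
    """
    cfg = dataset.config
    code = region_code or DEFAULT_REGION_CODES.get(region, f"CT {region.upper()}")
    base = pd.Timestamp(start_epoch)
    rng = np.random.default_rng([cfg.seed, 0x5EED])
    n = dataset.n
    n_neg = int(rng.binomial(n, cfg.negative_save_rate)) if cfg.negative_save_rate else 0

    n_rows = n + n_neg
    days = pd.bdate_range(base.normalize(), periods=n_rows // exams_per_day + 1)
    day_offset = base - base.normalize()

    exam_ids: list[str] = []
    starts: list[pd.Timestamp] = []
    saves: list[pd.Timestamp] = []
    for i in range(n):
        start = days[i // exams_per_day] + day_offset + pd.Timedelta(
            minutes=slot_minutes * (i % exams_per_day)
        )
        micro = int(round(dataset.durations[i] * _US_PER_MIN))
        exam_ids.append(f"SIM-{i:06d}")
        starts.append(start)
        saves.append(start + pd.Timedelta(microseconds=micro))
    for j in range(n_neg):
        i = n + j
        start = days[i // exams_per_day] + day_offset + pd.Timedelta(
            minutes=slot_minutes * (i % exams_per_day)
        )
        back = int(round(float(rng.uniform(1.0, 30.0)) * _US_PER_MIN))
        exam_ids.append(f"NEG-{j:06d}")
        starts.append(start)
        saves.append(start - pd.Timedelta(microseconds=back))

    frame = pd.DataFrame(
        {
            DEFAULT_COLUMNS["exam_id"]: exam_ids,
            DEFAULT_COLUMNS["region_code"]: code,
            DEFAULT_COLUMNS["dictation_start"]: [t.isoformat() for t in starts],
            DEFAULT_COLUMNS["first_save"]: [t.isoformat() for t in saves],
        }
    )
    truth = pd.DataFrame(
        {
            "exam_id": exam_ids,
            "component": list(dataset.labels) + ["negative_save"] * n_neg,
        }
    )
    return frame, truth


def write_dataset(
    dataset: LabeledDataset,
    out_dir,
    region: str = "head",
    **kwargs,
) -> tuple[Path, Path]:
    """Write timestamps.csv and labels.csv for a dataset; return the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame, truth = to_timestamp_table(dataset, region=region, **kwargs)
    ts_path = out / "timestamps.csv"
    lb_path = out / "labels.csv"
    frame.to_csv(ts_path, index=False)
    truth.to_csv(lb_path, index=False)
    return ts_path, lb_path
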