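"""Seedable synthetic datasets with the statistical structure of the study.

Six balanced classes, one per (harvest week, storage day) pair: weeks 7
("Green") and 8 ("Mature"), days 2, 4 and 7 after harvest.  The generator
encodes the complementarity of the two modalities:

* the 32-channel e-nose mean patterns of the three week-7 classes are far
  apart (each storage day activates a different channel block), while the
  three week-8 patterns are nearly coincident — a ripe fruit's headspace
  changes little over storage, so the e-nose alone resolves at most four
  groups;
* the acoustic firmness indices (FI, AFI) fall sharply between day 2 and
  days 4/7, with Green firmer than Mature on day 2 and the order reversed
  afterwards, so firmness resolves storage days within either week.

Fused, the six class means are mutually well separated; on the e-nose
block alone the week-8 means collapse into one cluster.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

N_CHANNELS = 32

#: Baseline-purge and sample-draw windows of one sniff cycle (seconds).
BASELINE_WINDOW = (0.0, 10.0)
DRAW_WINDOW = (10.0, 60.0)

#: Per-fruit acoustic index means (FI, AFI) for each (week, day) class,
#: in instrument index units.  Green fruit are firmer on day 2; by days 4
#: and 7 the order reverses as early-harvest fruit soften faster.
_ACOUSTIC_MEANS = {
    (7, 2): (27.71, 63.48),
    (7, 4): (7.213, 40.64),
    (7, 7): (6.463, 38.21),
    (8, 2): (22.25, 60.44),
    (8, 4): (8.975, 49.04),
    (8, 7): (8.751, 47.73),
}

DEFAULT_ENOSE_SD = 1.0
DEFAULT_ACOUSTIC_SD = 0.2
DEFAULT_N_PER_CLASS = 80
SNIFFS_PER_FRUIT = 5


@dataclass
class ClassSpec:
    """Population parameters of one (harvest week, storage day) class."""

    class_id: int
    harvest_week: int
    day: int
    enose_mean: np.ndarray
    acoustic_mean: np.ndarray
    enose_sd: float = DEFAULT_ENOSE_SD
    acoustic_sd: float = DEFAULT_ACOUSTIC_SD
    n_samples: int = DEFAULT_N_PER_CLASS

    def __post_init__(self) -> None:
        self.enose_mean = np.asarray(self.enose_mean, dtype=float)
        self.acoustic_mean = np.asarray(self.acoustic_mean, dtype=float)
        # zero sd is the noiseless limit, usable in tests; negative is invalid
        if self.enose_sd < 0 or self.acoustic_sd < 0:
            raise ValueError("class noise sds must be non-negative")
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")


@dataclass
class SniffTrace:
    """One sniff cycle: timed resistance recording of all 32 channels."""

    time: np.ndarray
    resistance: np.ndarray  # (n_samples, 32), positive
    baseline_window: tuple[float, float] = BASELINE_WINDOW
    draw_window: tuple[float, float] = DRAW_WINDOW
    sniff_index: int = 1


@dataclass(frozen=True)
class ToyCLNNFixture:
    """The printed 7-input / 3-neuron competitive-layer worked example."""

    inputs: np.ndarray  # (7, 2) rows p1..p7
    weights: np.ndarray  # (3, 2) rows w1..w3, unit norm
    learning_rate: float = 0.5

    @property
    def p(self) -> np.ndarray:
        return self.inputs

    @property
    def w(self) -> np.ndarray:
        return self.weights


def _default_enose_means() -> dict[tuple[int, int], np.ndarray]:
    """Fixed 32-channel mean smellprints obeying the separation structure.

    A common smooth base pattern carries the sensor-to-sensor response
    profile; each week-7 (Green) class additionally activates a distinct
    block of channels (volatile composition shifts with storage day while
    the fruit is still ripening), whereas the week-8 (Mature) classes
    differ only by a small alternating perturbation well inside the noise.
    """
    ch = np.arange(N_CHANNELS)
    base = 0.8 + 0.2 * np.sin(2 * np.pi * ch / N_CHANNELS)
    blocks = {2: slice(0, 10), 4: slice(10, 21), 7: slice(21, 32)}
    u = np.where(ch % 2 == 0, 1.0, -1.0) / np.sqrt(N_CHANNELS)
    means: dict[tuple[int, int], np.ndarray] = {}
    for day, blk in blocks.items():
        m = base.copy()
        m[blk] += 2.5
        means[(7, day)] = m
    means[(8, 2)] = base.copy()
    means[(8, 4)] = base + 0.2 * u
    means[(8, 7)] = base - 0.2 * u
    return means


def paper_default_classes(
    enose_sd: float = DEFAULT_ENOSE_SD,
    acoustic_sd: float = DEFAULT_ACOUSTIC_SD,
    n_per_class: int = DEFAULT_N_PER_CLASS,
) -> list[ClassSpec]:
    """The six default class specifications, ordered (wk7 d2, d4, d7, wk8 d2, d4, d7)."""
    enose = _default_enose_means()
    specs = []
    order = [(7, 2), (7, 4), (7, 7), (8, 2), (8, 4), (8, 7)]
    for cid, (week, day) in enumerate(order, start=1):
        specs.append(
            ClassSpec(
                class_id=cid,
                harvest_week=week,
                day=day,
                enose_mean=enose[(week, day)],
                acoustic_mean=np.array(_ACOUSTIC_MEANS[(week, day)]),
                enose_sd=enose_sd,
                acoustic_sd=acoustic_sd,
                n_samples=n_per_class,
            )
        )
    validate_class_specs(specs)
    return specs


def validate_class_specs(specs: list[ClassSpec]) -> None:
    """Check the structural invariants of a six-class configuration.

    Raises ``ValueError`` if the configuration does not have exactly six
    classes (one per week/day pair), if the three week-8 e-nose means are
    not nearly coincident (pairwise distance <= 0.5 * enose_sd), if the
    week-7 e-nose means are not well separated (>= 6 * enose_sd), or if
    classes differing in storage day are not separated acoustically
    (>= 6 * acoustic_sd).
    """
    if len(specs) != 6:
        raise ValueError(f"expected 6 class specs, got {len(specs)}")
    if any(s.enose_sd <= 0 or s.acoustic_sd <= 0 for s in specs):
        raise ValueError("study configuration requires strictly positive sds")
    pairs = {(s.harvest_week, s.day) for s in specs}
    if pairs != {(w, d) for w in (7, 8) for d in (2, 4, 7)}:
        raise ValueError("classes must cover each (week, day) pair exactly once")
    by_week = {7: [s for s in specs if s.harvest_week == 7],
               8: [s for s in specs if s.harvest_week == 8]}
    for i in range(3):
        for j in range(i + 1, 3):
            a, b = by_week[8][i], by_week[8][j]
            d = np.linalg.norm(a.enose_mean - b.enose_mean)
            if d > 0.5 * min(a.enose_sd, b.enose_sd):
                raise ValueError("week-8 e-nose means must nearly coincide")
            a, b = by_week[7][i], by_week[7][j]
            d = np.linalg.norm(a.enose_mean - b.enose_mean)
            if d < 6 * max(a.enose_sd, b.enose_sd):
                raise ValueError("week-7 e-nose means must be well separated")
    for i, a in enumerate(specs):
        for b in specs[i + 1:]:
            if a.day != b.day:
                d = np.linalg.norm(a.acoustic_mean - b.acoustic_mean)
                if d < 6 * max(a.acoustic_sd, b.acoustic_sd):
                    raise ValueError(
                        "acoustic means of classes differing in day must be "
                        ">= 6 acoustic sds apart"
                    )


def enose_channel_columns() -> list[str]:
    return [f"ch{k:02d}" for k in range(1, N_CHANNELS + 1)]


def generate_dataset(
    specs: list[ClassSpec] | None = None,
    seed: int = 0,
    sniffs_per_fruit: int = SNIFFS_PER_FRUIT,
    keep_first_sniff: bool = False,
) -> pd.DataFrame:
    """Draw a labelled feature table: e-nose block, acoustic block, labels.

    Each class contributes ``n_samples`` analysis rows organised as
    virtual fruits with ``sniffs_per_fruit`` repeated sniffs each; the
    first sniff of every fruit is flagged with ``sniff_index == 1`` and is
    emitted only when ``keep_first_sniff`` is set (so the downstream
    discard rule can be exercised).  Rows are drawn as class mean plus
    isotropic Gaussian noise per block.  Identical seed, identical output.

    Returns a DataFrame with columns
    ``fruit_id, class, sniff_index, ch01..ch32, FI, AFI``.
    """
    if specs is None:
        specs = paper_default_classes()
    if len(specs) != 6:
        raise ValueError("the default study design requires exactly 6 classes")
    if sniffs_per_fruit < 2:
        raise ValueError("need at least 2 sniffs per fruit")
    rng = np.random.default_rng(seed)
    kept = sniffs_per_fruit - 1
    frames = []
    for spec in specs:
        if spec.n_samples % kept:
            raise ValueError(
                f"n_samples={spec.n_samples} not divisible by the "
                f"{kept} retained sniffs per fruit"
            )
        n_fruit = spec.n_samples // kept
        rows_per_fruit = sniffs_per_fruit if keep_first_sniff else kept
        n_rows = n_fruit * rows_per_fruit
        enose = spec.enose_mean + rng.normal(0.0, spec.enose_sd, (n_rows, N_CHANNELS))
        acoustic = spec.acoustic_mean + rng.normal(0.0, spec.acoustic_sd, (n_rows, 2))
        first = 1 if keep_first_sniff else 2
        sniff_idx = np.tile(np.arange(first, sniffs_per_fruit + 1), n_fruit)
        fruit = np.repeat(
            [f"c{spec.class_id}f{j:02d}" for j in range(1, n_fruit + 1)],
            rows_per_fruit,
        )
        df = pd.DataFrame(enose, columns=enose_channel_columns())
        df.insert(0, "fruit_id", fruit)
        df.insert(1, "class", spec.class_id)
        df.insert(2, "sniff_index", sniff_idx)
        df["FI"] = acoustic[:, 0]
        df["AFI"] = acoustic[:, 1]
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def generate_sniff_trace(
    class_id: int,
    seed: int = 0,
    specs: list[ClassSpec] | None = None,
    noise_sd: float = 0.0,
    dt: float = 0.5,
    tau: float = 10.0,
    sniff_index: int = 1,
) -> SniffTrace:
    """Simulate one sniff cycle's raw 32-channel resistance recording.

    During the baseline purge the channels sit at their reference-gas
    resistance S0; from the draw onset each channel rises first-order,

        R(t) = S0 * (1 + A_ch * (1 - exp(-(t - t_draw) / tau))),

    with per-channel amplitude A_ch chosen so that the fractional response
    extracted downstream equals the class mean smellprint in the noiseless
    limit.  The default time constant (10 s) puts the response above 99 %
    of plateau by the end of the 50 s draw, matching a sensor that reaches
    steady state within the sniffing time.  ``noise_sd`` is the relative
    (multiplicative) Gaussian noise level.
    """
    if specs is None:
        specs = paper_default_classes()
    by_id = {s.class_id: s for s in specs}
    if class_id not in by_id:
        raise ValueError(f"unknown class_id {class_id}")
    spec = by_id[class_id]
    t0, t1 = BASELINE_WINDOW[0], DRAW_WINDOW[1]
    t_draw = DRAW_WINDOW[0]
    time = np.arange(t0, t1 + dt / 2, dt)
    ch = np.arange(N_CHANNELS)
    s0 = 100.0 * (1.0 + 0.25 * np.sin(2 * np.pi * ch / N_CHANNELS + 0.7))
    # Plateau correction: the draw ends at (t1 - t_draw)/tau time constants,
    # so divide out the unreached fraction to hit the class mean exactly.
    amp = spec.enose_mean / (1.0 - np.exp(-(t1 - t_draw) / tau))
    rise = np.clip(time[:, None] - t_draw, 0.0, None)
    resistance = s0[None, :] * (1.0 + amp[None, :] * (1.0 - np.exp(-rise / tau)))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        resistance = resistance * (1.0 + rng.normal(0.0, noise_sd, resistance.shape))
        resistance = np.clip(resistance, 1e-6, None)
    return SniffTrace(time=time, resistance=resistance, sniff_index=sniff_index)


def toy_clnn_fixture() -> ToyCLNNFixture:
    """The printed competitive-layer worked example: 7 inputs, 3 unit weights."""
    inputs = np.array(
        [
            [-0.198, 0.974],
            [0.196, 0.981],
            [0.988, -0.214],
            [0.824, -0.512],
            [0.524, -0.812],
            [-0.351, -0.875],
            [-0.725, -0.625],
        ]
    )
    weights = np.array(
        [
            [0.707, -0.707],
            [0.707, 0.707],
            [-1.000, 0.0],
        ]
    )
    return ToyCLNNFixture(inputs=inputs, weights=weights, learning_rate=0.5)


def separable_class_groups(
    specs: list[ClassSpec],
    use_enose: bool = True,
    use_acoustic: bool = True,
    threshold: float = 3.0,
) -> int:
    """Count distinguishable class groups from the noiseless means.

    Two classes are confusable when their mean separation, standardized by
    the per-block noise sd, is below ``threshold``; the count is the number
    of connected components of the confusability graph.  On the default
    configuration the e-nose block alone yields 4 groups (the three week-8
    classes collapse) while the fused blocks yield 6.
    """
    n = len(specs)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = specs[i], specs[j]
            d2 = 0.0
            if use_enose:
                d2 += float(np.sum((a.enose_mean - b.enose_mean) ** 2)) / (
                    max(a.enose_sd, b.enose_sd) ** 2
                )
            if use_acoustic:
                d2 += float(np.sum((a.acoustic_mean - b.acoustic_mean) ** 2)) / (
                    max(a.acoustic_sd, b.acoustic_sd) ** 2
                )
            if np.sqrt(d2) < threshold:
                parent[find(i)] = find(j)
    return len({find(i) for i in range(n)})


def save_dataset(df: pd.DataFrame, path: str | Path, seed: int,
                 specs: list[ClassSpec] | None = None) -> None:
    """Write a feature table as CSV with a JSON sidecar recording provenance."""
    path = Path(path)
    df.to_csv(path, index=False)
    sidecar = {
        "seed": seed,
        "n_rows": int(len(df)),
        "columns": list(df.columns),
    }
    if specs is not None:
        sidecar["classes"] = [
            {
                "class_id": s.class_id,
                "harvest_week": s.harvest_week,
                "day": s.day,
                "enose_sd": s.enose_sd,
                "acoustic_sd": s.acoustic_sd,
                "n_samples": s.n_samples,
            }
            for s in specs
        ]
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
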