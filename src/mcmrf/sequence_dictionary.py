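"""MRF-EPI transient-state signal simulation and dictionary generation.

The acquisition plays a train of spoiled gradient-echo EPI frames with
frame-varying flip angle, echo time and repetition time, interleaved with
global adiabatic inversion pulses.  Under perfect transverse spoiling the
longitudinal magnetization of a tissue with relaxation times (T1, T2*) obeys

    between events:   Mz(t + dt) = 1 + (Mz(t) - 1) * exp(-dt / T1)
    at an excitation: Mz <- Mz * cos(b1 * alpha_k)
    at an inversion:  Mz <- -eta * Mz

(all magnetizations normalized to the equilibrium value), and the magnitude
signal sampled at the echo of frame k is

    s_k = M0 * |Mz before the pulse| * sin(b1 * alpha_k) * exp(-TE_k / T2*),

where ``b1`` is the flip-angle efficiency (realized / nominal flip angle) and
``eta`` the inversion efficiency.  A dictionary tabulates these signal
evolutions, L2-normalized, on a logarithmic (T1, T2*) grid crossed with a
linear b1 grid, excluding the non-physical region T1 < T2*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SequenceTrain",
    "TissueParams",
    "DictionaryGrid",
    "Dictionary",
    "CompressedDictionary",
    "default_train",
    "simulate_signal",
    "simulate_signals",
    "build_grid",
    "build_dictionary",
    "compress",
]

# Nominal protocol ranges: flip angle 34-86 deg, TE 21-81.5 ms,
# TR 3530-6570 ms, roughly 3 global inversion pulses per minute.
FLIP_RANGE_DEG = (34.0, 86.0)
TE_RANGE_MS = (21.0, 81.5)
TR_RANGE_MS = (3530.0, 6570.0)
INVERSIONS_PER_MINUTE = 3.0

# Default dictionary grid: T1 30-4000 ms and T2* 5-3000 ms in 5% geometric
# steps, flip-angle efficiency 0.65-1.35 in steps of 0.05.
DEFAULT_T1_RANGE_MS = (30.0, 4000.0)
DEFAULT_T2STAR_RANGE_MS = (5.0, 3000.0)
DEFAULT_STEP_FRACTION = 0.05
DEFAULT_B1_RANGE = (0.65, 1.35)
DEFAULT_B1_STEP = 0.05


@dataclass(frozen=True)
class SequenceTrain:
    """Per-frame acquisition schedule of an MRF-EPI train.

    Times are in milliseconds; ``inversion_times_ms`` holds absolute times of
    global inversion pulses measured from the start of the train.
    ``slice_offset_ms`` is the delay of this slice's excitation within each TR
    (slice-interleaved EPI readout).
    """

    flip_angle_deg: np.ndarray
    te_ms: np.ndarray
    tr_ms: np.ndarray
    inversion_times_ms: np.ndarray = field(default_factory=lambda: np.empty(0))
    slice_offset_ms: float = 0.0
    inversion_efficiency: float = 1.0

    def __post_init__(self) -> None:
        for name in ("flip_angle_deg", "te_ms", "tr_ms", "inversion_times_ms"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.n_frames < 1:
            raise ValueError("a sequence train needs at least one frame")
        if not (self.flip_angle_deg.shape == self.te_ms.shape == self.tr_ms.shape):
            raise ValueError("flip_angle_deg, te_ms and tr_ms must have equal length")
        if np.any(self.te_ms >= self.tr_ms):
            raise ValueError("every TE must be shorter than its TR")
        inv = self.inversion_times_ms
        if inv.size and np.any(np.diff(inv) <= 0):
            raise ValueError("inversion times must be strictly increasing")
        if not 0.0 < self.inversion_efficiency <= 1.0:
            raise ValueError("inversion_efficiency must lie in (0, 1]")

    @property
    def n_frames(self) -> int:
        return int(self.flip_angle_deg.size)

    @property
    def duration_ms(self) -> float:
        """Total cumulative TR of the train."""
        return float(self.tr_ms.sum())

    def with_slice_offset(self, slice_offset_ms: float) -> "SequenceTrain":
        return SequenceTrain(
            self.flip_angle_deg,
            self.te_ms,
            self.tr_ms,
            self.inversion_times_ms,
            float(slice_offset_ms),
            self.inversion_efficiency,
        )

    def to_table(self) -> str:
        """Serialize as a plain-text table (header carries inversion times)."""
        lines = [
            "# inversion_times_ms: " + " ".join(f"{t:.12g}" for t in self.inversion_times_ms),
            f"# slice_offset_ms: {self.slice_offset_ms:.6g}",
            f"# inversion_efficiency: {self.inversion_efficiency:.6g}",
            "index\tflip_deg\tte_ms\ttr_ms",
        ]
        for k in range(self.n_frames):
            lines.append(
                f"{k}\t{self.flip_angle_deg[k]:.12g}\t{self.te_ms[k]:.12g}\t{self.tr_ms[k]:.12g}"
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_table(cls, text: str) -> "SequenceTrain":
        inversion_times: list[float] = []
        slice_offset = 0.0
        efficiency = 1.0
        flips: list[float] = []
        tes: list[float] = []
        trs: list[float] = []
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("inversion_times_ms:"):
                    inversion_times = [float(v) for v in body.split(":", 1)[1].split()]
                elif body.startswith("slice_offset_ms:"):
                    slice_offset = float(body.split(":", 1)[1])
                elif body.startswith("inversion_efficiency:"):
                    efficiency = float(body.split(":", 1)[1])
                continue
            if line.startswith("index"):
                continue
            _, flip, te, tr = line.split("\t")
            flips.append(float(flip))
            tes.append(float(te))
            trs.append(float(tr))
        return cls(
            np.array(flips), np.array(tes), np.array(trs),
            np.array(inversion_times), slice_offset, efficiency,
        )


@dataclass(frozen=True)
class TissueParams:
    """Relaxation parameters of a single tissue component."""

    t1_ms: float
    t2star_ms: float
    b1_eff: float = 1.0
    m0: float = 1.0

    def __post_init__(self) -> None:
        if min(self.t1_ms, self.t2star_ms, self.b1_eff) <= 0:
            raise ValueError("t1_ms, t2star_ms and b1_eff must be strictly positive")
        if self.t1_ms < self.t2star_ms:
            raise ValueError("dictionary convention requires t1_ms >= t2star_ms")
        if self.m0 < 0:
            raise ValueError("m0 must be non-negative")


def default_train(n_frames: int = 50, seed: int = 0) -> SequenceTrain:
    """Construct the reproducible default MRF-EPI train.

    Flip angles sweep 34-86 degrees as a half-sinusoid (endpoints rescaled so
    the extrema are hit exactly), TE ramps linearly 21-81.5 ms, TR linearly
    3530-6570 ms, and global inversion pulses are spaced uniformly so the
    count per minute of cumulative TR is as close as possible to 3.  The
    schedule is deterministic; ``seed`` is accepted for interface uniformity.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    lo, hi = FLIP_RANGE_DEG
    if n_frames == 1:
        flip = np.array([0.5 * (lo + hi)])
        te = np.array([TE_RANGE_MS[0]])
        tr = np.array([TR_RANGE_MS[0]])
    else:
        phase = np.sin(np.pi * np.arange(n_frames) / (n_frames - 1))
        phase = (phase - phase.min()) / (phase.max() - phase.min())
        flip = lo + (hi - lo) * phase
        te = np.linspace(*TE_RANGE_MS, n_frames)
        tr = np.linspace(*TR_RANGE_MS, n_frames)
    total_min = tr.sum() / 60000.0
    n_inv = int(round(INVERSIONS_PER_MINUTE * total_min))
    if n_inv > 0:
        spacing = tr.sum() / n_inv
        inversion_times = spacing * (0.5 + np.arange(n_inv))
    else:
        inversion_times = np.empty(0)
    return SequenceTrain(flip, te, tr, inversion_times)


def _event_schedule(train: SequenceTrain, slice_offset_ms: float):
    """Merged, time-ordered (time, kind, frame) events.

    kind 0 = inversion, 1 = excitation; an inversion coincident with an
    excitation is applied first.
    """
    frame_starts = np.concatenate([[0.0], np.cumsum(train.tr_ms)[:-1]])
    exc_times = frame_starts + slice_offset_ms
    events = [(t, 1, k) for k, t in enumerate(exc_times)]
    events += [(t, 0, -1) for t in train.inversion_times_ms]
    events.sort(key=lambda e: (e[0], e[1]))
    return events


def simulate_signals(
    train: SequenceTrain,
    t1_ms: np.ndarray,
    t2star_ms: np.ndarray,
    b1_eff: np.ndarray,
    slice_offset_ms: float | None = None,
) -> np.ndarray:
    """Vectorized transient-state simulation.

    Parameters are broadcast 1-D arrays of equal length n; returns the
    magnitude signal array of shape (n_frames, n) for unit M0.
    """
    t1 = np.atleast_1d(np.asarray(t1_ms, dtype=float))
    t2s = np.atleast_1d(np.asarray(t2star_ms, dtype=float))
    b1 = np.atleast_1d(np.asarray(b1_eff, dtype=float))
    t1, t2s, b1 = np.broadcast_arrays(t1, t2s, b1)
    if np.any(t1 <= 0) or np.any(t2s <= 0) or np.any(b1 <= 0):
        raise ValueError("relaxation times and b1 efficiency must be positive")
    offset = train.slice_offset_ms if slice_offset_ms is None else float(slice_offset_ms)

    alpha = np.deg2rad(train.flip_angle_deg)
    mz = np.ones_like(t1)
    signal = np.zeros((train.n_frames, t1.size))
    t_now = 0.0
    for t_event, kind, k in _event_schedule(train, offset):
        dt = t_event - t_now
        if dt > 0:
            mz = 1.0 + (mz - 1.0) * np.exp(-dt / t1)
        t_now = t_event
        if kind == 0:
            mz = -train.inversion_efficiency * mz
        else:
            a = b1 * alpha[k]
            signal[k] = np.abs(mz) * np.sin(a) * np.exp(-train.te_ms[k] / t2s)
            mz = mz * np.cos(a)
    return signal


def simulate_signal(
    train: SequenceTrain,
    tissue: TissueParams,
    slice_offset_ms: float | None = None,
) -> np.ndarray:
    """Magnitude signal evolution of one tissue (length ``train.n_frames``)."""
    sig = simulate_signals(
        train,
        np.array([tissue.t1_ms]),
        np.array([tissue.t2star_ms]),
        np.array([tissue.b1_eff]),
        slice_offset_ms,
    )
    return tissue.m0 * sig[:, 0]


@dataclass(frozen=True)
class DictionaryGrid:
    """Logarithmic (T1, T2*) grid crossed with a linear b1 grid.

    ``pair_t1_idx`` / ``pair_t2s_idx`` index the admissible (T1 >= T2*) pairs
    into the two geometric series; all b1 values are combined with every pair.
    """

    t1_values_ms: np.ndarray
    t2star_values_ms: np.ndarray
    b1_values: np.ndarray
    pair_t1_idx: np.ndarray
    pair_t2s_idx: np.ndarray

    @property
    def n_pairs(self) -> int:
        return int(self.pair_t1_idx.size)

    @property
    def n_b1(self) -> int:
        return int(self.b1_values.size)

    @property
    def n_entries(self) -> int:
        return self.n_pairs * self.n_b1

    @property
    def pair_t1_ms(self) -> np.ndarray:
        return self.t1_values_ms[self.pair_t1_idx]

    @property
    def pair_t2star_ms(self) -> np.ndarray:
        return self.t2star_values_ms[self.pair_t2s_idx]

    def nearest_pair(self, t1_ms: float, t2star_ms: float) -> int:
        """Index of the admissible pair closest in log-space."""
        d = (np.log(self.pair_t1_ms) - np.log(t1_ms)) ** 2
        d += (np.log(self.pair_t2star_ms) - np.log(t2star_ms)) ** 2
        return int(np.argmin(d))

    def nearest_b1(self, b1: float) -> int:
        return int(np.argmin(np.abs(self.b1_values - b1)))


def _geometric_series(lo: float, hi: float, step_fraction: float) -> np.ndarray:
    """Values lo * (1+step)^k for k = 0, 1, ... while <= hi (with float slack)."""
    n = int(np.floor(np.log(hi / lo) / np.log1p(step_fraction) + 1e-9)) + 1
    return lo * (1.0 + step_fraction) ** np.arange(n)


def build_grid(
    t1_range_ms: tuple[float, float] = DEFAULT_T1_RANGE_MS,
    t2star_range_ms: tuple[float, float] = DEFAULT_T2STAR_RANGE_MS,
    step_fraction: float = DEFAULT_STEP_FRACTION,
    b1_range: tuple[float, float] = DEFAULT_B1_RANGE,
    b1_step: float = DEFAULT_B1_STEP,
) -> DictionaryGrid:
    """Build the dictionary grid; pairs with T1 < T2* are excluded."""
    if step_fraction <= 0 or b1_step <= 0:
        raise ValueError("step sizes must be positive")
    if min(t1_range_ms[0], t2star_range_ms[0], b1_range[0]) <= 0:
        raise ValueError("grid ranges must be positive")
    t1_vals = _geometric_series(*t1_range_ms, step_fraction)
    t2s_vals = _geometric_series(*t2star_range_ms, step_fraction)
    n_b1 = int(np.floor((b1_range[1] - b1_range[0]) / b1_step + 1e-9)) + 1
    b1_vals = b1_range[0] + b1_step * np.arange(n_b1)
    i1, i2 = np.meshgrid(np.arange(t1_vals.size), np.arange(t2s_vals.size), indexing="ij")
    admissible = t1_vals[i1] >= t2s_vals[i2]
    pair_t1 = i1[admissible]
    pair_t2s = i2[admissible]
    if pair_t1.size == 0:
        raise ValueError("grid is empty: no admissible (t1 >= t2*) pairs")
    return DictionaryGrid(t1_vals, t2s_vals, b1_vals, pair_t1, pair_t2s)


@dataclass(frozen=True)
class Dictionary:
    """L2-normalized signal dictionary for one slice timing.

    ``atoms`` has shape (n_frames, n_entries) with entries ordered b1-major:
    entry ``j`` corresponds to b1 index ``j // n_pairs`` and pair index
    ``j % n_pairs``.  ``norms`` holds each atom's pre-normalization L2 norm
    (unit-M0 signal scale), needed to recover M0 from match inner products.
    """

    atoms: np.ndarray
    norms: np.ndarray
    grid: DictionaryGrid
    train: SequenceTrain
    slice_index: int = 0

    @property
    def n_frames(self) -> int:
        return int(self.atoms.shape[0])

    @property
    def n_entries(self) -> int:
        return int(self.atoms.shape[1])

    def entry_params(self, j: int | np.ndarray):
        """(t1_ms, t2star_ms, b1) of entry/entries ``j``."""
        g = self.grid
        b1_idx, pair_idx = np.divmod(j, g.n_pairs)
        return (
            g.pair_t1_ms[pair_idx],
            g.pair_t2star_ms[pair_idx],
            g.b1_values[b1_idx],
        )

    def b1_block(self, b1_idx: int) -> np.ndarray:
        """Atom block (n_frames, n_pairs) for one b1 value."""
        p = self.grid.n_pairs
        return self.atoms[:, b1_idx * p : (b1_idx + 1) * p]


def build_dictionary(
    train: SequenceTrain,
    grid: DictionaryGrid,
    slice_index: int = 0,
    slice_offset_ms: float | None = None,
) -> Dictionary:
    """Simulate and L2-normalize one atom per (T1, T2*, b1) grid entry."""
    if grid.n_entries == 0:
        raise ValueError("cannot build a dictionary from an empty grid")
    offset = train.slice_offset_ms if slice_offset_ms is None else float(slice_offset_ms)
    t1 = np.tile(grid.pair_t1_ms, grid.n_b1)
    t2s = np.tile(grid.pair_t2star_ms, grid.n_b1)
    b1 = np.repeat(grid.b1_values, grid.n_pairs)
    atoms = simulate_signals(train, t1, t2s, b1, offset)
    norms = np.linalg.norm(atoms, axis=0)
    if np.any(norms == 0):
        raise ValueError("degenerate grid entry produced an all-zero signal")
    return Dictionary(atoms / norms, norms, grid, train.with_slice_offset(offset), slice_index)


@dataclass(frozen=True)
class CompressedDictionary:
    """Rank-truncated singular-subspace representation of a dictionary.

    ``projector`` (rank, n_frames) maps frame-space signals into the
    compressed space; ``atoms`` are the projected (still unit-norm up to the
    truncation error) dictionary columns.
    """

    atoms: np.ndarray
    norms: np.ndarray
    grid: DictionaryGrid
    projector: np.ndarray
    singular_values: np.ndarray
    slice_index: int = 0

    @property
    def rank(self) -> int:
        return int(self.projector.shape[0])

    @property
    def n_pairs(self) -> int:
        return self.grid.n_pairs

    def compress_data(self, signals: np.ndarray) -> np.ndarray:
        """Project frame-space signals (..., n_frames) into rank space."""
        return signals @ self.projector.T

    def b1_block(self, b1_idx: int) -> np.ndarray:
        p = self.grid.n_pairs
        return self.atoms[:, b1_idx * p : (b1_idx + 1) * p]

    def entry_params(self, j):
        g = self.grid
        b1_idx, pair_idx = np.divmod(j, g.n_pairs)
        return g.pair_t1_ms[pair_idx], g.pair_t2star_ms[pair_idx], g.b1_values[b1_idx]


def compress(dictionary: Dictionary, rank: int) -> CompressedDictionary:
    """SVD-truncate the dictionary to ``rank`` temporal components.

    Matching and multi-component fitting in the compressed space agree with
    frame space up to the discarded singular spectrum.  ``rank=1`` collapses
    nearly all atoms onto one direction and is unsupported for analysis.
    """
    if not 1 <= rank <= dictionary.n_frames:
        raise ValueError("rank must lie in [1, n_frames]")
    gram = dictionary.atoms @ dictionary.atoms.T
    eigval, eigvec = np.linalg.eigh(gram)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    basis = eigvec[:, order[:rank]]
    projector = basis.T
    return CompressedDictionary(
        atoms=projector @ dictionary.atoms,
        norms=dictionary.norms,
        grid=dictionary.grid,
        projector=projector,
        singular_values=np.sqrt(eigval),
        slice_index=dictionary.slice_index,
    )
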