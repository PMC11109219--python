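"""Core containers shared across the pipeline.

All arrays are plain :class:`numpy.ndarray`; containers are light dataclasses
that carry the metadata the downstream stages need (sampling rate, baseline
window, parcel labels, ...). Time is handled in samples internally; seconds
relative to the first tone onset are used at the interfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ROI_NAMES = ("LHG", "RHG", "LHP", "RHP", "ACC", "MC")
CONDITIONS = ("M", "NT1", "NT2", "NT3", "NT4")


@dataclass
class SequenceDesign:
    """Trial-level description of the five-condition sequence design.

    Each trial presents a five-tone melody.  ``M`` trials replay a memorised
    sequence; ``NTk`` trials copy the first k tones of a memorised sequence
    and change every tone from position k+1 onward (``varied_from`` is that
    1-based tone index).
    """

    n_trials_per_condition: int
    conditions: np.ndarray  # per-trial condition label, dtype=object/str
    tone_onsets_ms: np.ndarray  # 5 onsets, ms from first tone
    tone_duration_ms: float
    epoch_ms: float
    baseline_ms: float
    sfreq: float
    pitch_sequences: np.ndarray  # trials x 5 integer pitches
    varied_from: np.ndarray  # per-trial 1-based first varied tone, 0 for M
    variation_strategy: np.ndarray  # per-trial strategy label ('' for M)

    @property
    def n_trials(self) -> int:
        return len(self.conditions)

    @property
    def n_times(self) -> int:
        return int(round(self.epoch_ms / 1000.0 * self.sfreq))

    @property
    def time_zero(self) -> int:
        """Sample index of the first tone onset."""
        return int(round(self.baseline_ms / 1000.0 * self.sfreq))

    def times_s(self) -> np.ndarray:
        """Time axis in seconds relative to the first tone onset."""
        return (np.arange(self.n_times) - self.time_zero) / self.sfreq

    def tone_onset_samples(self) -> np.ndarray:
        return self.time_zero + np.round(
            self.tone_onsets_ms / 1000.0 * self.sfreq
        ).astype(int)


@dataclass
class SourceGrid:
    """Volumetric source grid with an anatomical-style parcellation."""

    coords: np.ndarray  # voxels x 3, mm
    spacing_mm: float
    parcel_label: np.ndarray  # per-voxel parcel name (str)
    roi_names: tuple[str, ...] = ROI_NAMES

    @property
    def n_voxels(self) -> int:
        return self.coords.shape[0]

    def roi_voxels(self, roi: str) -> np.ndarray:
        return np.flatnonzero(self.parcel_label == roi)


@dataclass
class Leadfield:
    """Forward model: gain from unit dipoles to sensors.

    ``gain`` keeps the three free orientations per source; ``reduced`` is the
    single-orientation gain (sources x channels) after SVD orientation
    reduction and is ``None`` until :func:`seqmeg.beamformer.reduce_orientation`
    has been applied.
    """

    gain: np.ndarray  # sources x 3 x channels
    grid: SourceGrid
    reduced: np.ndarray | None = None  # sources x channels

    @property
    def n_sources(self) -> int:
        return self.gain.shape[0]

    @property
    def n_channels(self) -> int:
        return self.gain.shape[2]


@dataclass
class SensorEpochs:
    """Epoched sensor data: trials x channels x time."""

    data: np.ndarray
    labels: np.ndarray  # per-trial condition
    sfreq: float
    baseline_window: tuple[int, int]  # half-open sample range
    channel_types: np.ndarray  # per-channel 'mag' | 'grad'
    time_zero: int  # sample index of first tone onset

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def times_s(self) -> np.ndarray:
        return (np.arange(self.n_times) - self.time_zero) / self.sfreq

    def pick(self, channel_type: str) -> "SensorEpochs":
        """Return a copy restricted to one channel type."""
        mask = self.channel_types == channel_type
        return SensorEpochs(
            data=self.data[:, mask, :],
            labels=self.labels,
            sfreq=self.sfreq,
            baseline_window=self.baseline_window,
            channel_types=self.channel_types[mask],
            time_zero=self.time_zero,
        )


@dataclass
class GroundTruth:
    """Record of every effect injected by the generator, for recovery tests."""

    source_ts: np.ndarray  # trials x ROI x time, noise free
    effect_windows: dict
    true_model_id: int
    covariate: float
    subject_seed: int


@dataclass
class SensorCovariance:
    """Sensor covariance with diagonal loading."""

    C: np.ndarray
    n_samples: int
    regularization: float


@dataclass
class BeamformerWeights:
    """LCMV spatial-filter weights, one row per source."""

    W: np.ndarray  # sources x channels
    normalized: bool = False
    sign_flip: np.ndarray | None = None  # per-source +-1 set by align_sign


@dataclass
class SourceTimeSeries:
    """Reconstructed source activity ("neural activity index").

    ``evoked`` mode holds condition averages: ``data`` maps condition ->
    sources x time.  ``induced`` mode keeps single trials: trials x sources
    x time plus the trial labels.
    """

    data: dict | np.ndarray
    mode: str  # 'evoked' | 'induced'
    grid: SourceGrid
    sfreq: float
    time_zero: int
    labels: np.ndarray | None = None


@dataclass
class ROITimeSeries:
    """Parcel-aggregated series: subjects x conditions x ROI x time."""

    data: np.ndarray
    roi_names: tuple[str, ...]
    conditions: tuple[str, ...]
    sfreq: float
    time_zero: int
    leakage_corrected: bool = False


@dataclass
class DecodingResult:
    """Pairwise decoding output for one subject."""

    accuracy: np.ndarray  # time
    patterns: np.ndarray | None  # channels x time
    tg_matrix: np.ndarray | None  # train-time x test-time
    n_folds: int
    n_reps: int
    pair: tuple[str, str]


@dataclass
class ClusterResult:
    """Clusters surviving cluster-based Monte-Carlo correction."""

    clusters: list  # dicts: indices, size, sign, mcs_p, significant
    null_max_sizes: np.ndarray
    alpha_binarize: float
    n_perm: int
    mcs_p_level: float

    @property
    def significant(self) -> list:
        return [c for c in self.clusters if c["significant"]]


@dataclass
class TFRepresentation:
    """Morlet-wavelet power: (trials x) frequencies x time."""

    power: np.ndarray
    freqs: np.ndarray
    sfreq: float
    baseline_window: tuple[int, int] | None = None
    corrected: bool = False
    edge_mask: np.ndarray | None = None  # freqs x time, True where edge-safe


@dataclass
class ModelSpec:
    """One directed network architecture over the six ROIs."""

    id: int
    nodes: tuple[str, ...]
    forward_edges: tuple[tuple[str, str], ...]
    backward_edges: tuple[tuple[str, str], ...]
    input_nodes: tuple[str, ...] = ("LHG", "RHG")

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        return self.forward_edges + self.backward_edges

    def adjacency(self) -> np.ndarray:
        """Boolean node x node matrix, entry (i, j) = edge j -> i allowed."""
        idx = {n: i for i, n in enumerate(self.nodes)}
        A = np.zeros((len(self.nodes), len(self.nodes)), dtype=bool)
        for src, dst in self.edges:
            A[idx[dst], idx[src]] = True
        return A


@dataclass
class ModelFit:
    """Laplace fit of one architecture to one ROI window."""

    m: int  # ModelSpec id
    theta_mean: np.ndarray
    theta_cov: np.ndarray
    F: float
    accuracy_term: float
    complexity_term: float
    window: tuple[int, int, int]  # tone index, start sample, stop sample
    sigma2: float = np.nan
    param_names: list = field(default_factory=list)


@dataclass
class BMSResult:
    """Random-effects Bayesian model selection over an evidence matrix."""

    posterior_prob: np.ndarray  # per model, expected frequency
    xp: np.ndarray  # exceedance probability
    pxp: np.ndarray  # protected exceedance probability
    bor: float
    dirichlet_alpha: np.ndarray
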