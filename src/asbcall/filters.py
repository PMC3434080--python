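"""Two-stage variant filtering: heuristic hard rules and a Gaussian-mixture
model filter calibrated on calls overlapping trusted known sites.

Hard-filter rules (each sets its own flag; a call passes iff no flag is
set, and no call is ever deleted):

* ``cluster``     - more than ``cluster_max`` calls inside any
  ``cluster_window`` bp window (all calls in the window are flagged)
* ``nonunique``   - more than ``nonunique_max_fraction`` of the reads
  overlapping the site are not uniquely aligned (MAPQ below the
  genotyper's uniqueness cutoff)
* ``low_qual``    - site quality strictly below ``min_qual``
* ``repeat``      - position inside the supplied repeat mask
* ``near_indel``  - within ``indel_pad`` bp (inclusive) of a read-supported
  insertion/deletion position
* ``high_cov``    - position inside a region of exceptionally high
  coverage (above the ``high_cov_quantile`` depth quantile)

The model filter fits a full-covariance Gaussian mixture over call
annotations using the calls that overlap a known-sites list as training
data, then thresholds the log-density so that a fixed fraction
(``gmm_sensitivity``, default 99%) of the training calls is retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture

from .core import VariantCall, merge_positions

log = logging.getLogger(__name__)

DEFAULT_ANNOTATIONS = ("qd", "dp", "sb", "mq", "gq")

FLAG_CLUSTER = "cluster"
FLAG_NONUNIQUE = "nonunique"
FLAG_LOW_QUAL = "low_qual"
FLAG_REPEAT = "repeat"
FLAG_NEAR_INDEL = "near_indel"
FLAG_HIGH_COV = "high_cov"
FLAG_MODEL = "model"
ALL_FLAGS = (FLAG_CLUSTER, FLAG_NONUNIQUE, FLAG_LOW_QUAL, FLAG_REPEAT,
             FLAG_NEAR_INDEL, FLAG_HIGH_COV, FLAG_MODEL)


@dataclass
class FilterConfig:
    cluster_window: int = 10
    cluster_max: int = 2
    nonunique_max_fraction: float = 0.10
    min_qual: float = 50.0
    indel_pad: int = 5
    high_cov_quantile: float = 0.999
    repeat_mask: dict = field(default_factory=dict)  # chrom -> [(start, end)]
    gmm_components: int = 2
    gmm_sensitivity: float = 0.99
    gmm_min_training: int = 50
    annotation_keys: tuple = DEFAULT_ANNOTATIONS

    def validate(self) -> None:
        if self.cluster_window <= 0:
            raise ValueError("cluster_window must be positive")
        for name, frac in (("nonunique_max_fraction", self.nonunique_max_fraction),
                           ("gmm_sensitivity", self.gmm_sensitivity)):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name}={frac} outside [0, 1]")


@dataclass
class ModelFilter:
    """Fitted mixture-density filter over call annotations."""

    gmm: GaussianMixture
    annotation_keys: tuple
    score_threshold: float
    dropped_keys: tuple = ()

    @property
    def weights(self) -> np.ndarray:
        return self.gmm.weights_

    @property
    def means(self) -> np.ndarray:
        return self.gmm.means_

    @property
    def covariances(self) -> np.ndarray:
        return self.gmm.covariances_

    def scores(self, calls: list[VariantCall]) -> np.ndarray:
        return self.gmm.score_samples(_annotation_matrix(
            calls, self.annotation_keys))


def detect_indel_positions(gap_events: dict, min_support: int = 2) -> set:
    """Positions where at least ``min_support`` reads show an indel gap.

    ``gap_events`` maps ``(chrom, position)`` to supporting read count as
    produced by :func:`asbcall.genotyper.collect_gap_events`.
    """
    return {key for key, n in gap_events.items() if n >= min_support}


def high_coverage_regions(depths: dict, quantile: float = 0.999) -> list:
    """Intervals of exceptionally high coverage.

    The depth threshold is the given quantile of depths over *covered*
    positions (pooled across contigs); positions strictly above it are
    merged into maximal half-open intervals ``(chrom, start, end)``.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError(f"quantile {quantile} outside (0, 1)")
    covered = np.concatenate([d[d > 0] for d in depths.values()]) \
        if depths else np.array([])
    if covered.size == 0:
        return []
    threshold = np.quantile(covered, quantile)
    out = []
    for chrom, d in depths.items():
        for s, e in merge_positions(np.flatnonzero(d > threshold)):
            out.append((chrom, s, e))
    return out


def _interval_lookup(intervals) -> dict:
    by_chrom: dict = {}
    for chrom, s, e in intervals:
        by_chrom.setdefault(chrom, []).append((s, e))
    return {
        c: (np.array([s for s, _ in sorted(iv)]),
            np.array([e for _, e in sorted(iv)]))
        for c, iv in by_chrom.items()
    }


def _in_lookup(lookup: dict, chrom: str, pos: int) -> bool:
    if chrom not in lookup:
        return False
    starts, ends = lookup[chrom]
    i = int(np.searchsorted(starts, pos, side="right")) - 1
    return i >= 0 and pos < ends[i]


def hard_filter(
    calls: list[VariantCall],
    config: FilterConfig | None = None,
    indel_positions: set = frozenset(),
    high_cov_intervals: list = (),
) -> list[VariantCall]:
    """Assign hard-filter flags to every call (rules are independent).

    Calls must be sorted by (chrom, position). Flags are added to
    ``filter_flags`` in place and the list is returned; applying the
    filter twice is a no-op.
    """
    cfg = config or FilterConfig()
    cfg.validate()
    order = [(c.chrom, c.pos) for c in calls]
    if order != sorted(order):
        raise ValueError("hard_filter requires calls sorted by position")

    repeat_lookup = _interval_lookup(
        (chrom, s, e)
        for chrom, ivs in (cfg.repeat_mask or {}).items() for s, e in ivs
    )
    highcov_lookup = _interval_lookup(high_cov_intervals)
    indels_by_chrom: dict = {}
    for chrom, pos in indel_positions:
        indels_by_chrom.setdefault(chrom, []).append(pos)
    indels_by_chrom = {c: np.sort(np.array(v)) for c, v in
                       indels_by_chrom.items()}

    # cluster rule: every call inside an offending window gets flagged
    for i, call in enumerate(calls):
        j = i
        while (j + 1 < len(calls)
               and calls[j + 1].chrom == call.chrom
               and calls[j + 1].pos < call.pos + cfg.cluster_window):
            j += 1
        if j - i + 1 > cfg.cluster_max:
            for k in range(i, j + 1):
                calls[k].filter_flags.add(FLAG_CLUSTER)

    for call in calls:
        nuf = call.annotations.get("nonunique_frac", 0.0)
        if nuf > cfg.nonunique_max_fraction:
            call.filter_flags.add(FLAG_NONUNIQUE)
        if call.qual < cfg.min_qual:
            call.filter_flags.add(FLAG_LOW_QUAL)
        if _in_lookup(repeat_lookup, call.chrom, call.pos):
            call.filter_flags.add(FLAG_REPEAT)
        if _in_lookup(highcov_lookup, call.chrom, call.pos):
            call.filter_flags.add(FLAG_HIGH_COV)
        near = indels_by_chrom.get(call.chrom)
        if near is not None and near.size:
            k = int(np.searchsorted(near, call.pos))
            dists = [abs(int(near[m]) - call.pos)
                     for m in (k - 1, k) if 0 <= m < near.size]
            if dists and min(dists) <= cfg.indel_pad:
                call.filter_flags.add(FLAG_NEAR_INDEL)
    return calls


def _annotation_matrix(calls, keys) -> np.ndarray:
    rows = []
    for c in calls:
        try:
            rows.append([float(c.annotations[k]) for k in keys])
        except KeyError as exc:
            raise ValueError(
                f"call {c.chrom}:{c.pos + 1} lacks annotation {exc}; "
                "annotation schema mismatch"
            ) from None
    return np.asarray(rows, dtype=float)


def train_model_filter(
    calls: list[VariantCall],
    known_sites: set,
    config: FilterConfig | None = None,
    random_state: int = 0,
) -> ModelFilter | None:
    """Fit the mixture model on calls overlapping the known-sites list.

    ``known_sites`` is a set of ``(chrom, pos, alt)`` tuples. The score
    threshold is set so the configured fraction of training calls is
    retained (scores at or above the threshold). Returns ``None`` with a
    warning when fewer than ``gmm_min_training`` calls overlap known
    sites; zero-variance annotation dimensions are dropped with a warning
    before fitting.
    """
    cfg = config or FilterConfig()
    cfg.validate()
    training = [c for c in calls if (c.chrom, c.pos, c.alt) in known_sites]
    if len(training) < cfg.gmm_min_training:
        log.warning(
            "model filter not trained: %d known-site calls < required %d",
            len(training), cfg.gmm_min_training)
        return None

    keys = list(cfg.annotation_keys)
    X = _annotation_matrix(training, keys)
    variances = X.var(axis=0)
    dropped = tuple(k for k, v in zip(keys, variances) if v == 0.0)
    if dropped:
        log.warning("dropping zero-variance annotation dimensions: %s",
                    ", ".join(dropped))
        keys = [k for k in keys if k not in dropped]
        if not keys:
            log.warning("model filter not trained: all annotations degenerate")
            return None
        X = X[:, variances > 0.0]

    gmm = GaussianMixture(
        n_components=min(cfg.gmm_components, len(training)),
        covariance_type="full", reg_covar=1e-6, n_init=1,
        random_state=random_state,
    ).fit(X)
    scores = gmm.score_samples(X)
    threshold = float(np.quantile(scores, 1.0 - cfg.gmm_sensitivity,
                                  method="higher"))
    retained = float(np.mean(scores >= threshold))
    log.info("model filter trained on %d calls (%d dims); retention %.4f",
             len(training), X.shape[1], retained)
    return ModelFilter(gmm, tuple(keys), threshold, dropped)


def apply_model_filter(
    calls: list[VariantCall], model: ModelFilter | None
) -> list[VariantCall]:
    """Flag calls scoring below the trained threshold with ``model``.

    With ``model=None`` (training fell back) no flags are added.
    """
    if model is None:
        return calls
    if not calls:
        return calls
    scores = model.scores(calls)
    for call, s in zip(calls, scores):
        if s < model.score_threshold:
            call.filter_flags.add(FLAG_MODEL)
    return calls
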