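"""Synthetic-data generators with planted ground truth.

Every input class consumed by the analysis modules can be generated here with
a known answer, so each downstream procedure is testable without any recorded
data: round-robin contest logs from a latent dominance model, fiber-photometry
trials with planted baseline deviations, miniscope ROI pre/post matrices with
planted activated/inhibited fractions, postsynaptic-current traces with
planted event times and amplitudes, and single-nucleus count matrices with
planted gene-set expression shifts and deliberately injected QC violations.

All generators are deterministic given their ``seed`` argument.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hierkit.gsea import CountMatrix, GeneSetCollection, DEFAULT_GENE_CLASSES

logger = logging.getLogger(__name__)

__all__ = [
    "DominanceWorld",
    "PlantedTraceTruth",
    "PlantedExpressionTruth",
    "TraceSet",
    "CONTEST_COLUMNS",
    "simulate_tournament",
    "simulate_random_log",
    "simulate_photometry_trial",
    "simulate_roi_matrix",
    "simulate_psc_trace",
    "simulate_counts",
]

#: Contest-log CSV schema shared across the package.
CONTEST_COLUMNS = [
    "group_id",
    "tournament",
    "round_robin",
    "contest_idx",
    "animal_a",
    "animal_b",
    "winner",
    "duration_s",
    "defensive_a_s",
    "defensive_b_s",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class DominanceWorld:
    """Latent dominance model generating tournament outcomes.

    Each animal carries a latent dominance score; animal *a* beats *b* with
    probability ``logistic(steepness * (score_a - score_b))`` (Bradley–Terry
    form), and the realized outcome is inverted with probability
    ``upset_rate`` to model intrinsic unpredictability.
    """

    animal_ids: list[str]
    latent_dominance: list[float]
    steepness: float = 1.0
    upset_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.animal_ids)) != len(self.animal_ids):
            raise ValueError("duplicate animal ids")
        if len(self.animal_ids) != len(self.latent_dominance):
            raise ValueError("one latent score per animal required")
        if not 0.0 <= self.upset_rate <= 1.0:
            raise ValueError("upset_rate must be in [0, 1]")
        if not self.steepness > 0:
            raise ValueError("steepness must be > 0")


@dataclass
class PlantedTraceTruth:
    """Ground truth planted into a synthetic trace or ROI matrix."""

    onset_times: list[float] = field(default_factory=list)
    roi_labels: list[str] = field(default_factory=list)
    event_times: list[float] = field(default_factory=list)
    event_amplitudes: list[float] = field(default_factory=list)


@dataclass
class PlantedExpressionTruth:
    """Ground truth planted into a synthetic count matrix.

    ``perturbed_sets`` maps a gene-set name to ``{condition: log-scale mean
    shift}``; ``qc_violations`` lists ``(nucleus_index, rule)`` pairs injected
    so QC filters can be exercised (rules: mito/umi/hemoglobin/ieg).
    """

    perturbed_sets: dict[str, dict[str, float]] = field(default_factory=dict)
    qc_violations: list[tuple[int, str]] = field(default_factory=list)


@dataclass
class TraceSet:
    """Uniformly sampled trace with annotated behavioral events.

    ``events`` holds event name -> time (s); conventionally ``tube_entry``
    and ``middle_meeting``.
    """

    values: np.ndarray
    fs: float
    events: dict[str, float] = field(default_factory=dict)
    baseline_window_s: float = 30.0
    baseline_mean: float | None = None
    baseline_sd: float | None = None

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.fs

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.fs


# ---------------------------------------------------------------------------
# tournaments
# ---------------------------------------------------------------------------


def _round_robin_schedule(animal_ids: list[str], n_round_robins: int, rng: np.random.Generator):
    """Yield (round_robin, animal_a, animal_b) covering each unordered pair once
    per round robin, with roles swapped on odd round robins so that each
    tournament (two consecutive round robins) covers all ordered pairs once.
    Pair order within a round robin is lexicographic then seed-shuffled.
    """
    ids = sorted(animal_ids)
    pairs = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1 :]]
    for rr in range(n_round_robins):
        order = rng.permutation(len(pairs))
        for k in order:
            a, b = pairs[k]
            yield (rr, a, b) if rr % 2 == 0 else (rr, b, a)


def simulate_tournament(
    world: DominanceWorld,
    n_round_robins: int = 2,
    group_size: int | None = None,
    group_id: str = "g1",
) -> pd.DataFrame:
    """Simulate a contest log for ``n_round_robins`` round robins.

    Within each tournament (two consecutive round robins) every unique pair
    meets twice with first/second roles swapped, i.e. every ordered pair
    exactly once: a group of four yields 12 contests per tournament.  Winners
    are drawn from the world's logistic outcome model, then inverted with
    probability ``world.upset_rate``.

    Defensive durations are also generated: the contest loser accrues more
    defensive time on average, so the defensive index downstream correlates
    with losing.

    Returns a tidy DataFrame with columns :data:`CONTEST_COLUMNS`.
    """
    n = len(world.animal_ids)
    if group_size is not None and group_size != n:
        raise ValueError("group_size does not match world.animal_ids")
    if n < 2:
        raise ValueError("group_size must be >= 2")
    if n_round_robins < 1:
        raise ValueError("n_round_robins must be >= 1")
    if n == 3:
        # For trios the ordered-pair rule yields 6 contests per tournament; the
        # alternative convention of 9 interactions per trio tournament is not
        # emulated here.
        logger.info("trio group: generating 6 contests per tournament (ordered-pair rule)")

    rng = np.random.default_rng(world.seed)
    latent = dict(zip(world.animal_ids, world.latent_dominance))
    rows = []
    for idx, (rr, a, b) in enumerate(_round_robin_schedule(world.animal_ids, n_round_robins, rng)):
        p_a = 1.0 / (1.0 + np.exp(-world.steepness * (latent[a] - latent[b])))
        winner = a if rng.random() < p_a else b
        if world.upset_rate and rng.random() < world.upset_rate:
            winner = b if winner == a else a
        loser_extra = rng.gamma(4.0, 5.0)
        base = rng.gamma(2.0, 2.0, size=2)
        def_a = base[0] + (loser_extra if winner == b else 0.0)
        def_b = base[1] + (loser_extra if winner == a else 0.0)
        rows.append(
            {
                "group_id": group_id,
                "tournament": rr // 2,
                "round_robin": rr,
                "contest_idx": idx,
                "animal_a": a,
                "animal_b": b,
                "winner": winner,
                "duration_s": float(rng.gamma(3.0, 10.0)),
                "defensive_a_s": float(def_a),
                "defensive_b_s": float(def_b),
            }
        )
    return pd.DataFrame(rows, columns=CONTEST_COLUMNS)


def simulate_random_log(template: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Replace each winner in ``template`` by a fair coin flip on its pair.

    The schedule (pairs, ordering, round robins) is preserved exactly; only
    outcomes are randomized.  This is the random-outcome null against which
    observed stability and consistency are compared.
    """
    if template.shape[0] == 0:
        raise ValueError("template log is empty")
    rng = np.random.default_rng(seed)
    out = template.copy()
    flips = rng.random(len(out)) < 0.5
    out["winner"] = np.where(flips, out["animal_a"], out["animal_b"])
    return out


# ---------------------------------------------------------------------------
# photometry / miniscope
# ---------------------------------------------------------------------------


def simulate_photometry_trial(
    fs: float = 200.0,
    baseline_s: float = 30.0,
    trial_s: float = 20.0,
    onset_s: float | None = None,
    step_sd_multiple: float = 10.0,
    noise_sd: float = 1.0,
    direction: int = 1,
    meeting_s: float | None = None,
    seed: int = 0,
) -> tuple[TraceSet, PlantedTraceTruth]:
    """Simulate a single photometry trial with an optional planted deviation.

    The recording starts with ``baseline_s`` of Gaussian noise, the animal
    enters the tube at ``t = baseline_s``, and the trial lasts ``trial_s``
    more seconds.  If ``onset_s`` (seconds after tube entry) is given, a
    sustained step of magnitude ``step_sd_multiple * noise_sd`` and sign
    ``direction`` is added from the onset to the end of the trial.
    ``middle_meeting`` defaults to the midpoint of the trial.
    """
    if fs <= 0:
        raise ValueError("fs must be > 0")
    if onset_s is not None and not (0 <= onset_s <= trial_s):
        raise ValueError("onset_s outside trial")
    rng = np.random.default_rng(seed)
    n = int(round((baseline_s + trial_s) * fs))
    values = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    truth = PlantedTraceTruth()
    if onset_s is not None:
        start = int(round((baseline_s + onset_s) * fs))
        values[start:] += np.sign(direction) * step_sd_multiple * noise_sd if noise_sd > 0 else np.sign(direction) * step_sd_multiple
        truth.onset_times = [onset_s]
    events = {
        "tube_entry": baseline_s,
        "middle_meeting": baseline_s + (meeting_s if meeting_s is not None else trial_s / 2.0),
    }
    return TraceSet(values=values, fs=fs, events=events, baseline_window_s=baseline_s), truth


def simulate_roi_matrix(
    n_rois: int,
    frac_activated: float = 0.0,
    frac_inhibited: float = 0.0,
    effect_sd_multiple: float = 6.0,
    null_sd: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, PlantedTraceTruth]:
    """Simulate per-ROI pre/post mean activity around a first encounter.

    Post-minus-pre differences are null Gaussian (sd ``null_sd``) for
    persistent ROIs and shifted by ``+/- effect_sd_multiple * null_sd`` for the
    planted activated/inhibited fractions.  Returns ``(pre, post, truth)``
    with ``truth.roi_labels`` giving the planted class per ROI.
    """
    if frac_activated < 0 or frac_inhibited < 0:
        raise ValueError("fractions must be non-negative")
    if frac_activated + frac_inhibited > 1:
        raise ValueError("frac_activated + frac_inhibited must be <= 1")
    rng = np.random.default_rng(seed)
    n_act = int(round(n_rois * frac_activated))
    n_inh = int(round(n_rois * frac_inhibited))
    labels = ["activated"] * n_act + ["inhibited"] * n_inh + ["persistent"] * (n_rois - n_act - n_inh)
    rng.shuffle(labels)
    pre = rng.normal(0.0, 1.0, size=n_rois)
    diff = rng.normal(0.0, null_sd, size=n_rois)
    shift = np.array(
        [effect_sd_multiple * null_sd if l == "activated" else -effect_sd_multiple * null_sd if l == "inhibited" else 0.0 for l in labels]
    )
    post = pre + diff + shift
    return pre, post, PlantedTraceTruth(roi_labels=labels)


# ---------------------------------------------------------------------------
# postsynaptic currents
# ---------------------------------------------------------------------------


def psc_kernel(fs: float, rise_ms: float, decay_ms: float, length_ms: float | None = None) -> np.ndarray:
    """Unit-amplitude difference-of-exponentials transient sampled at ``fs``.

    ``exp(-t/decay) - exp(-t/rise)``, peak-normalized to 1.  Default length is
    ``5 * decay_ms``.
    """
    if rise_ms >= decay_ms:
        raise ValueError("rise time must be shorter than decay time")
    if length_ms is None:
        length_ms = 5.0 * decay_ms
    t = np.arange(0, length_ms / 1000.0, 1.0 / fs)
    k = np.exp(-t / (decay_ms / 1000.0)) - np.exp(-t / (rise_ms / 1000.0))
    peak = k.max()
    return k / peak if peak > 0 else k


def simulate_psc_trace(
    duration_s: float = 60.0,
    fs: float = 20_000.0,
    event_rate: float = 2.0,
    amp_mean: float = 20.0,
    amp_sd: float = 4.0,
    rise_ms: float = 0.5,
    decay_ms: float = 2.0,
    noise_sd: float = 2.0,
    polarity: str = "excitatory",
    seed: int = 0,
) -> tuple[np.ndarray, PlantedTraceTruth]:
    """Simulate a voltage-clamp current trace with Poisson synaptic events.

    Event times follow a homogeneous Poisson process at ``event_rate``; each
    event is a difference-of-exponentials transient of amplitude drawn from
    ``N(amp_mean, amp_sd)`` (truncated positive), riding on Gaussian noise.
    Excitatory events are negative-going (inward current at -70 mV) and
    inhibitory events positive-going (outward at 0 mV); planted amplitudes in
    the returned truth are stored rectified (positive pA).
    """
    if rise_ms >= decay_ms:
        raise ValueError("rise time must be shorter than decay time")
    if polarity not in {"excitatory", "inhibitory"}:
        raise ValueError("polarity must be 'excitatory' or 'inhibitory'")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    trace = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    n_events = rng.poisson(event_rate * duration_s)
    times = np.sort(rng.uniform(0, duration_s, size=n_events))
    amps = np.abs(rng.normal(amp_mean, amp_sd, size=n_events))
    kernel = psc_kernel(fs, rise_ms, decay_ms)
    sign = -1.0 if polarity == "excitatory" else 1.0
    for t0, a in zip(times, amps):
        i0 = int(round(t0 * fs))
        seg = kernel[: n - i0]
        trace[i0 : i0 + len(seg)] += sign * a * seg
    return trace, PlantedTraceTruth(event_times=list(times), event_amplitudes=list(amps))


# ---------------------------------------------------------------------------
# single-nucleus counts
# ---------------------------------------------------------------------------


def default_gene_universe(n_genes: int, sets: GeneSetCollection | None = None) -> list[str]:
    """Gene-name universe containing QC sentinel classes, any gene-set members,
    and numbered filler genes up to ``n_genes``."""
    sentinels = (
        [f"mt-Nd{i}" for i in range(1, 5)]
        + ["Hba-a1", "Hbb-bs"]
        + list(DEFAULT_GENE_CLASSES["ieg"])
    )
    names: list[str] = list(dict.fromkeys(sentinels))
    if sets is not None:
        for members in sets.sets.values():
            for g in members:
                if g not in names:
                    names.append(g)
    i = 0
    while len(names) < n_genes:
        name = f"gene{i:05d}"
        if name not in names:
            names.append(name)
        i += 1
    if len(names) > n_genes:
        raise ValueError(f"n_genes={n_genes} too small for sentinels and set members ({len(names)} needed)")
    return names


def simulate_counts(
    n_genes: int,
    n_nuclei: int,
    conditions: list[str],
    sets: GeneSetCollection,
    truth: PlantedExpressionTruth | None = None,
    clusters: list[str] | None = None,
    base_mean: float = 1.0,
    dispersion: float = 0.5,
    sentinel_expression: float = 0.05,
    seed: int = 0,
) -> CountMatrix:
    """Simulate a genes x nuclei count matrix with planted set shifts.

    Counts follow a gamma–Poisson (negative-binomial) model: per-gene base
    means are log-normal, and genes belonging to a perturbed set have their
    mean multiplied by ``exp(shift)`` in nuclei of the shifted condition.
    Conditions (and clusters, default one cluster ``c1``) are assigned
    round-robin across nuclei.  QC sentinel genes (mitochondrial, hemoglobin,
    immediate early) are expressed at a low baseline (``sentinel_expression``
    times the typical mean) so that clean nuclei pass the QC thresholds; QC
    violations listed in the truth are injected afterwards by inflating the
    relevant sentinel-gene or total counts.
    """
    truth = truth or PlantedExpressionTruth()
    for name in truth.perturbed_sets:
        if name not in sets:
            raise ValueError(f"perturbed set {name!r} not in collection")
    rng = np.random.default_rng(seed)
    genes = default_gene_universe(n_genes, sets)
    gene_idx = {g: i for i, g in enumerate(genes)}
    condition = np.array([conditions[i % len(conditions)] for i in range(n_nuclei)], dtype=object)
    clusters = clusters or ["c1"]
    cluster = np.array([clusters[(i // len(conditions)) % len(clusters)] for i in range(n_nuclei)], dtype=object)

    base = rng.lognormal(mean=np.log(base_mean), sigma=0.6, size=n_genes)
    ieg_names = set(DEFAULT_GENE_CLASSES["ieg"])
    sentinel = np.array(
        [g.startswith(("mt-", "Hba", "Hbb")) or g in ieg_names for g in genes]
    )
    base[sentinel] *= sentinel_expression
    log_shift = np.zeros((n_genes, n_nuclei))
    for set_name, shifts in truth.perturbed_sets.items():
        rows = [gene_idx[g] for g in sets.sets[set_name] if g in gene_idx]
        for cond, shift in shifts.items():
            cols = np.flatnonzero(condition == cond)
            log_shift[np.ix_(rows, cols)] += shift
    mu = base[:, None] * np.exp(log_shift)
    # gamma-Poisson mixture == negative binomial with shape 1/dispersion
    lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
    counts = rng.poisson(lam)

    for nucleus, rule in truth.qc_violations:
        total = max(int(counts[:, nucleus].sum()), 1)
        if rule == "mito":
            rows = [i for i, g in enumerate(genes) if g.startswith("mt-")]
            counts[rows, nucleus] += total  # mito fraction -> ~0.5
        elif rule == "umi":
            counts[:, nucleus] += rng.poisson(25_000 / n_genes, size=n_genes) + 1
        elif rule == "hemoglobin":
            rows = [i for i, g in enumerate(genes) if g.startswith(("Hba", "Hbb"))]
            counts[rows, nucleus] += max(int(0.05 * total), 10)
        elif rule == "ieg":
            rows = [i for i, g in enumerate(genes) if g in set(DEFAULT_GENE_CLASSES["ieg"])]
            counts[rows, nucleus] += max(int(0.05 * total), 10)
        else:
            raise ValueError(f"unknown QC rule {rule!r}")

    barcodes = [f"cell{i:05d}" for i in range(n_nuclei)]
    return CountMatrix(counts=counts, genes=genes, barcodes=barcodes, condition=condition, cluster=cluster)
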