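"""Group statistics, pipeline orchestration, reporting and the CLI.

The headline comparison is a paired two-tailed t-test on composite scores
of the same subjects before vs after stimulation (the two "groups" are the
same nine animals), run separately for the time and frequency domains with
no multiple-testing correction — two raw p-values are reported.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml
from scipy import stats as spstats

from .errors import Dtw100Error, PipelineError, ValidationError
from .preprocess import ReferencePair, build_reference, preprocess_and_average, preprocess_trials
from .scoring import (
    ScoreCard,
    calibrate_A,
    composite_score,
    dtw100_score,
    pair_norm_distances,
    write_score_table,
)
from .signal_io import Modality, RunConfig, SignalTrace, load_config, read_trials
from .spectral import pair_norm_distances_spectral
from .synthetic_data import CohortSpec, generate_cohort, write_study

__all__ = [
    "GroupComparison",
    "StudySample",
    "StudyResult",
    "summarize",
    "paired_t_test",
    "run_study",
    "run_pipeline",
    "run_synthetic_study",
    "render_report",
    "main",
]

log = logging.getLogger(__name__)

DOMAINS = ("time", "frequency")


@dataclass
class GroupComparison:
    """Paired pre/post comparison of composite scores in one domain."""

    domain: str
    pre_scores: tuple[float, ...]
    post_scores: tuple[float, ...]
    mean_pre: float
    sd_pre: float
    mean_post: float
    sd_post: float
    mean_increase: float
    sd_increase: float
    t_statistic: float
    p_value: float
    n: int


@dataclass
class StudySample:
    """One subject's preprocessed, trial-averaged pair in one phase."""

    sample_id: str
    phase: str  # "pre" | "post"
    lfp: SignalTrace
    emg: SignalTrace


@dataclass
class StudyResult:
    """Everything a run produces: per-sample cards, group comparisons, the As."""

    scorecards: list[ScoreCard]
    comparisons: list[GroupComparison]
    coefficients: dict[str, float]


def summarize(scores) -> tuple[float, float]:
    """Arithmetic mean and sample standard deviation (n-1 denominator)."""
    arr = np.asarray(list(scores), dtype=np.float64)
    if arr.size < 2:
        raise ValidationError("need at least 2 values for a standard deviation")
    return float(arr.mean()), float(arr.std(ddof=1))


def paired_t_test(pre, post, domain: str = "time") -> GroupComparison:
    """Two-tailed paired t-test on post - pre differences (df = n - 1).

    Zero variance of the differences leaves the t statistic undefined; the
    p-value is then reported as exactly 1 (all differences zero) or 0
    (constant non-zero shift), with a warning.
    """
    pre = np.asarray(list(pre), dtype=np.float64)
    post = np.asarray(list(post), dtype=np.float64)
    if pre.size != post.size:
        raise ValidationError(f"pre ({pre.size}) and post ({post.size}) must pair up")
    if pre.size < 2:
        raise ValidationError("paired t-test needs at least 2 pairs")
    diff = post - pre
    n = diff.size
    sd_diff = float(diff.std(ddof=1))
    mean_diff = float(diff.mean())
    if sd_diff == 0.0:
        warnings.warn(
            "paired differences have zero variance; t statistic undefined",
            stacklevel=2,
        )
        t = 0.0 if mean_diff == 0.0 else float(np.sign(mean_diff)) * np.inf
        p = 1.0 if mean_diff == 0.0 else 0.0
    else:
        t, p = spstats.ttest_rel(post, pre)
        t, p = float(t), float(p)
    mean_pre, sd_pre = summarize(pre)
    mean_post, sd_post = summarize(post)
    return GroupComparison(
        domain=domain,
        pre_scores=tuple(map(float, pre)),
        post_scores=tuple(map(float, post)),
        mean_pre=mean_pre,
        sd_pre=sd_pre,
        mean_post=mean_post,
        sd_post=sd_post,
        mean_increase=mean_diff,
        sd_increase=sd_diff,
        t_statistic=t,
        p_value=p,
        n=n,
    )


# ---------------------------------------------------------------------------
# Study orchestration (in-memory)


def _distance_table(samples, ref, cfg, domains):
    table = {}
    for s in samples:
        entry = {}
        try:
            if "time" in domains:
                entry["time"] = pair_norm_distances(s.lfp, s.emg, ref, cfg)
            if "frequency" in domains:
                entry["frequency"] = pair_norm_distances_spectral(s.lfp, s.emg, ref, cfg)
        except Dtw100Error as exc:
            raise PipelineError(f"scoring failed for sample {s.sample_id!r} ({s.phase}): {exc}") from exc
        table[(s.sample_id, s.phase)] = entry
    return table


def run_study(
    cfg: RunConfig,
    reference: ReferencePair,
    samples: list[StudySample],
    domains=DOMAINS,
) -> StudyResult:
    """Score every sample against the reference and compare pre vs post.

    The scoring coefficient is taken from ``cfg.coefficient_A`` when set
    (shared by both domains); otherwise each domain is calibrated on the
    pre-phase samples with a floor score of 0, falling back to all samples
    if no pre-phase samples exist.
    """
    domains = tuple(domains)
    for d in domains:
        if d not in DOMAINS:
            raise ValidationError(f"unknown domain {d!r}")
    table = _distance_table(samples, ref=reference, cfg=cfg, domains=domains)

    coefficients: dict[str, float] = {}
    for domain in domains:
        if cfg.coefficient_A is not None:
            coefficients[domain] = cfg.coefficient_A
            continue
        pool = [
            d
            for s in samples
            if s.phase == "pre"
            for d in table[(s.sample_id, s.phase)][domain]
        ]
        if not pool:
            pool = [d for key in table for d in table[key][domain]]
        if not pool:
            raise ValidationError(
                "coefficient A is unset and there are no samples to calibrate on"
            )
        coefficients[domain] = calibrate_A(pool, floor_score=0.0)
        log.info("calibrated %s-domain A = %.6g on %d distances", domain,
                 coefficients[domain], len(pool))

    cards: list[ScoreCard] = []
    for s in samples:
        for domain in domains:
            dl, de = table[(s.sample_id, s.phase)][domain]
            A = coefficients[domain]
            ls, es = dtw100_score(dl, A), dtw100_score(de, A)
            cards.append(
                ScoreCard(
                    sample_id=s.sample_id,
                    lfp_score=ls,
                    emg_score=es,
                    composite=composite_score(ls, es, cfg.composite_weight),
                    domain=domain,
                    phase=s.phase,
                    coefficient_A=A,
                )
            )
    cards.sort(key=lambda c: (c.domain, c.phase, c.sample_id))

    comparisons = []
    by_key = {(c.domain, c.phase, c.sample_id): c.composite for c in cards}
    pre_ids = sorted({c.sample_id for c in cards if c.phase == "pre"})
    post_ids = {c.sample_id for c in cards if c.phase == "post"}
    paired_ids = [sid for sid in pre_ids if sid in post_ids]
    if len(paired_ids) >= 2:
        for domain in domains:
            comparisons.append(
                paired_t_test(
                    [by_key[(domain, "pre", sid)] for sid in paired_ids],
                    [by_key[(domain, "post", sid)] for sid in paired_ids],
                    domain=domain,
                )
            )
    return StudyResult(scorecards=cards, comparisons=comparisons, coefficients=coefficients)


def prepare_samples(cfg, normal_cohort, pre_cohort, post_cohort):
    """Preprocess synthetic cohorts into a reference pair and study samples."""
    lfp_sets = [preprocess_trials(lfp, cfg) for lfp, _ in normal_cohort]
    emg_sets = [preprocess_trials(emg, cfg) for _, emg in normal_cohort]
    reference = build_reference(lfp_sets, emg_sets)
    samples = []
    for phase, cohort in (("pre", pre_cohort), ("post", post_cohort)):
        for i, (lfp, emg) in enumerate(cohort):
            samples.append(
                StudySample(
                    sample_id=f"s{i}",
                    phase=phase,
                    lfp=preprocess_and_average(lfp, cfg),
                    emg=preprocess_and_average(emg, cfg),
                )
            )
    return reference, samples


def run_synthetic_study(
    cfg: RunConfig,
    *,
    n_reference: int = 30,
    n_subjects: int = 9,
    n_trials: int = 30,
    seed: int | None = None,
    domains=DOMAINS,
) -> StudyResult:
    """Generate the default synthetic study and run the full pipeline on it."""
    seed = cfg.seed if seed is None else seed
    common = dict(n_trials=n_trials, rate=cfg.rate, epoch_seconds=cfg.epoch_seconds, seed=seed)
    normal = generate_cohort(CohortSpec("normal", n_subjects=n_reference, **common))
    pre = generate_cohort(CohortSpec("bcao_pre", n_subjects=n_subjects, **common))
    post = generate_cohort(CohortSpec("bcao_post", n_subjects=n_subjects, **common))
    reference, samples = prepare_samples(cfg, normal, pre, post)
    return run_study(cfg, reference, samples, domains=domains)


# ---------------------------------------------------------------------------
# File-based pipeline


def _load_subject_pair(base: Path, entry: dict, rate: float):
    try:
        lfp = read_trials(base / entry["lfp"], rate=rate, modality=Modality.LFP)
        emg = read_trials(base / entry["emg"], rate=rate, modality=Modality.EMG)
    except KeyError as exc:
        raise ValidationError(f"manifest entry {entry.get('id', '?')!r} lacks key {exc}") from exc
    return lfp, emg


def run_pipeline(
    cfg: RunConfig,
    manifest_path,
    out_dir,
    domains=DOMAINS,
) -> StudyResult:
    """Full file-based pipeline: manifest -> preprocess -> scores -> report.

    The manifest is YAML with a ``reference`` list (normal-cohort subjects)
    and a ``subjects`` list (entries with ``id``, ``phase`` pre/post, and
    per-modality trial-matrix paths, relative to the manifest).  Writes
    ``scores.csv``, ``comparisons.csv`` and ``report.txt`` to ``out_dir``.
    """
    manifest_path = Path(manifest_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = yaml.safe_load(manifest_path.read_text())
    if not isinstance(manifest, dict) or "reference" not in manifest:
        raise ValidationError(f"{manifest_path}: manifest must map 'reference' and 'subjects'")
    base = manifest_path.parent
    rate = float(manifest.get("rate", cfg.rate))

    try:
        ref_pairs = [_load_subject_pair(base, e, rate) for e in manifest["reference"]]
        lfp_sets = [preprocess_trials(lfp, cfg) for lfp, _ in ref_pairs]
        emg_sets = [preprocess_trials(emg, cfg) for _, emg in ref_pairs]
        reference = build_reference(lfp_sets, emg_sets)
    except Dtw100Error as exc:
        raise PipelineError(f"reference construction failed: {exc}") from exc

    samples = []
    for entry in manifest.get("subjects", []) or []:
        sid, phase = str(entry.get("id")), str(entry.get("phase"))
        if phase not in ("pre", "post"):
            raise ValidationError(f"subject {sid!r}: phase must be 'pre' or 'post', got {phase!r}")
        try:
            lfp, emg = _load_subject_pair(base, entry, rate)
            samples.append(
                StudySample(
                    sample_id=sid,
                    phase=phase,
                    lfp=preprocess_and_average(lfp, cfg),
                    emg=preprocess_and_average(emg, cfg),
                )
            )
        except Dtw100Error as exc:
            raise PipelineError(f"preprocessing failed for sample {sid!r} ({phase}): {exc}") from exc

    if samples:
        result = run_study(cfg, reference, samples, domains=domains)
    else:
        result = StudyResult(scorecards=[], comparisons=[], coefficients={})

    write_score_table(result.scorecards, out_dir / "scores.csv")
    write_comparisons(result.comparisons, out_dir / "comparisons.csv")
    (out_dir / "report.txt").write_text(render_report(result, n_reference=len(ref_pairs)))
    log.info("pipeline outputs written to %s", out_dir)
    return result


def write_comparisons(comparisons, path) -> None:
    lines = [
        "domain,n,mean_pre,sd_pre,mean_post,sd_post,mean_increase,sd_increase,t_statistic,p_value"
    ]
    for c in comparisons:
        lines.append(
            f"{c.domain},{c.n},{c.mean_pre:.10g},{c.sd_pre:.10g},"
            f"{c.mean_post:.10g},{c.sd_post:.10g},{c.mean_increase:.10g},"
            f"{c.sd_increase:.10g},{c.t_statistic:.10g},{c.p_value:.10g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def render_report(result: StudyResult, n_reference: int | None = None) -> str:
    """Human-readable plain-text summary of a study."""
    out = ["DTW-100 cortico-muscular coupling report", "=" * 41]
    if n_reference is not None:
        out.append(f"reference cohort: {n_reference} subject average(s)")
    if not result.scorecards:
        out.append("no subject cohorts were scored (reference only).")
        return "\n".join(out) + "\n"
    for domain, A in result.coefficients.items():
        out.append(f"{domain}-domain coefficient A = {A:.6g}")
    out.append("")
    out.append(f"{'sample':<10}{'phase':<7}{'domain':<11}{'LFP':>8}{'EMG':>8}{'composite':>11}")
    for c in result.scorecards:
        out.append(
            f"{c.sample_id:<10}{c.phase:<7}{c.domain:<11}"
            f"{c.lfp_score:>8.1f}{c.emg_score:>8.1f}{c.composite:>11.1f}"
        )
    out.append("")
    if not result.comparisons:
        out.append("no paired pre/post cohort; group comparison skipped.")
    for c in result.comparisons:
        stars = "***" if c.p_value < 0.001 else ("**" if c.p_value < 0.01 else
                                                 ("*" if c.p_value < 0.05 else "n.s."))
        out.append(
            f"{c.domain} domain (n={c.n} pairs): "
            f"pre {c.mean_pre:.1f} ± {c.sd_pre:.1f}, post {c.mean_post:.1f} ± {c.sd_post:.1f}, "
            f"increase {c.mean_increase:.1f} ± {c.sd_increase:.1f}, "
            f"t = {c.t_statistic:.2f}, p = {c.p_value:.3g} {stars}"
        )
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Command-line interface


def _cfg_from(config, coefficient_a, seed, decimate):
    cfg = load_config(config) if config else RunConfig()
    updates = {}
    if coefficient_a is not None:
        updates["coefficient_A"] = coefficient_a
    if seed is not None:
        updates["seed"] = seed
    if decimate is not None:
        updates["time_decimate"] = decimate
    if updates:
        from dataclasses import replace

        cfg = replace(cfg, **updates)
    return cfg


def _domains(domain: str):
    return DOMAINS if domain == "both" else (domain,)


@click.group(name="dtw100")
def cli():
    """Percentage scoring of cortico-muscular coupling via dynamic time warping."""


@cli.command()
@click.option("--out-dir", required=True, type=click.Path(file_okay=False))
@click.option("--seed", default=0, show_default=True, type=int)
@click.option("--n-reference", default=30, show_default=True, type=int,
              help="Normal subjects forming the healthy reference.")
@click.option("--n-subjects", default=9, show_default=True, type=int,
              help="Subjects in each of the pre/post cohorts.")
@click.option("--n-trials", default=30, show_default=True, type=int)
@click.option("--rate", default=2000.0, show_default=True, type=float)
@click.option("--epoch-seconds", default=4.0, show_default=True, type=float)
def simulate(out_dir, seed, n_reference, n_subjects, n_trials, rate, epoch_seconds):
    """Generate a synthetic study (normal + pre/post cohorts) on disk."""
    manifest = write_study(
        out_dir, seed,
        n_reference=n_reference, n_subjects=n_subjects, n_trials=n_trials,
        rate=rate, epoch_seconds=epoch_seconds,
    )
    click.echo(f"wrote synthetic study manifest: {manifest}")


@cli.command()
@click.option("--manifest", required=True, type=click.Path(exists=True, dir_okay=False))
@click.option("--config", type=click.Path(exists=True, dir_okay=False))
@click.option("--out-dir", required=True, type=click.Path(file_okay=False))
@click.option("--domain", type=click.Choice(["time", "frequency", "both"]), default="both",
              show_default=True)
@click.option("--coefficient-a", type=float, default=None,
              help="Pin the scoring coefficient instead of calibrating it.")
@click.option("--seed", type=int, default=None)
@click.option("--decimate", type=int, default=None,
              help="Time-domain decimation factor before DTW.")
def score(manifest, config, out_dir, domain, coefficient_a, seed, decimate):
    """Score a manifest's subjects against its reference cohort."""
    cfg = _cfg_from(config, coefficient_a, seed, decimate)
    result = run_pipeline(cfg, manifest, out_dir, domains=_domains(domain))
    for dom, A in result.coefficients.items():
        click.echo(f"{dom}-domain A = {A:.6g}")
    click.echo(f"score tables written to {out_dir}")


@cli.command()
@click.option("--scores", "scores_path", required=True,
              type=click.Path(exists=True, dir_okay=False),
              help="A scores.csv produced by the score/report commands.")
@click.option("--out-dir", type=click.Path(file_okay=False), default=None)
def compare(scores_path, out_dir):
    """Paired pre/post t-tests from an existing score table."""
    df = pd.read_csv(scores_path)
    needed = {"sample_id", "phase", "domain", "composite"}
    if not needed.issubset(df.columns):
        raise ValidationError(f"{scores_path}: score table must have columns {sorted(needed)}")
    comparisons = []
    for domain, group in df.groupby("domain", sort=True):
        pre = group[group.phase == "pre"].set_index("sample_id")["composite"]
        post = group[group.phase == "post"].set_index("sample_id")["composite"]
        ids = sorted(set(pre.index) & set(post.index))
        if len(ids) >= 2:
            comparisons.append(paired_t_test(pre[ids], post[ids], domain=domain))
    if not comparisons:
        raise ValidationError("no domain has >= 2 paired pre/post samples")
    for c in comparisons:
        click.echo(
            f"{c.domain}: n={c.n}, increase {c.mean_increase:.2f} ± {c.sd_increase:.2f}, "
            f"t = {c.t_statistic:.3f}, p = {c.p_value:.3g}"
        )
    if out_dir:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        write_comparisons(comparisons, Path(out_dir) / "comparisons.csv")
        click.echo(f"comparison table written to {out_dir}")


@cli.command()
@click.option("--manifest", required=True, type=click.Path(exists=True, dir_okay=False))
@click.option("--config", type=click.Path(exists=True, dir_okay=False))
@click.option("--out-dir", required=True, type=click.Path(file_okay=False))
@click.option("--domain", type=click.Choice(["time", "frequency", "both"]), default="both",
              show_default=True)
@click.option("--coefficient-a", type=float, default=None)
@click.option("--seed", type=int, default=None)
@click.option("--decimate", type=int, default=None)
def report(manifest, config, out_dir, domain, coefficient_a, seed, decimate):
    """Full pipeline: preprocess, score, compare, and print the text report."""
    cfg = _cfg_from(config, coefficient_a, seed, decimate)
    result = run_pipeline(cfg, manifest, out_dir, domains=_domains(domain))
    click.echo((Path(out_dir) / "report.txt").read_text(), nl=False)


def main(argv=None) -> int:
    """Console entry point with the documented exit codes (0/2/1)."""
    try:
        cli.main(args=argv, standalone_mode=False)
    except click.exceptions.Abort:
        return 1
    except click.UsageError as exc:
        exc.show()
        return 2
    except ValidationError as exc:
        click.echo(f"validation error: {exc}", err=True)
        return 2
    except (Dtw100Error, OSError) as exc:
        click.echo(f"error: {exc}", err=True)
        return 1
    return 0
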