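"""Study records, file schemas, replication reports, and synthetic series.

A :class:`StudyRecord` tags a design-specific payload with a role
(``original`` / ``replication`` / ``combined``) and a label.  Records can be
read from and written to JSON (all designs) or CSV (one record per row;
contingency rows carry the four cell counts).  ``run_replication_report``
turns a homogeneous record list into a structured report: per-study Bayes
factors, the complete (pooled) Bayes factor, the replication Bayes factor
in both directions, credible-interval summaries where the design supports
them, and the classical parity statistic.

The synthetic generators draw study series from known truth so every
pipeline is testable without external data; all randomness flows through an
explicit seed.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import core
from .binomial import (
    BetaPrior,
    BinomialCount,
    beta_credible_interval,
    bf10_binomial,
    bf10_binomial_onesided,
    binomial_two_sided_p,
    update_beta,
)
from .contingency import CrossTable, DirichletPrior, bf10_contingency, pearson_chi_square, pool_tables
from .ttest import (
    EffectSizePrior,
    TStatSummary,
    TwoSampleSummary,
    bf10_ttest,
    bf10_ttest_onesided,
    pool_two_sample_summaries,
    t_from_summaries,
)

logger = logging.getLogger("repbf")

ROLES = ("original", "replication", "combined")


@dataclass(frozen=True)
class StudyRecord:
    """A design-tagged study payload with its role in the replication analysis.

    The optional ``combined`` role carries an externally supplied pooled
    summary (e.g. a published pooled t statistic) for designs whose
    per-study payloads are not poolable on their own.
    """

    design: str
    role: str
    payload: object
    label: str = ""

    def __post_init__(self) -> None:
        if self.design not in core.DESIGNS:
            raise ValueError(f"unknown design {self.design!r}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        ok = {
            "binomial": (BinomialCount,),
            "ttest": (TwoSampleSummary, TStatSummary),
            "contingency": (CrossTable,),
        }[self.design]
        if not isinstance(self.payload, ok):
            raise ValueError(
                f"payload type {type(self.payload).__name__} does not match "
                f"design {self.design!r}"
            )


@dataclass(frozen=True)
class ReportConfig:
    """Prior settings and reporting conventions for a replication report."""

    beta_prior: BetaPrior = field(default_factory=lambda: BetaPrior(1.0, 1.0))
    effect_prior: EffectSizePrior = field(default_factory=EffectSizePrior)
    dirichlet_prior: DirichletPrior = field(default_factory=DirichletPrior)
    theta0: float = 0.5
    credible_level: float = 0.95
    rounding: int = 3
    direction_policy: str = "two_sided"

    def __post_init__(self) -> None:
        if self.rounding < 0:
            raise ValueError("rounding must be nonnegative")
        if self.direction_policy not in ("two_sided", "order_restricted_by_original"):
            raise ValueError(f"unknown direction policy {self.direction_policy!r}")


# ---------------------------------------------------------------------------
# serialization


def _payload_to_dict(rec: StudyRecord) -> dict:
    p = rec.payload
    if isinstance(p, BinomialCount):
        return {"successes": p.successes, "trials": p.trials}
    if isinstance(p, TStatSummary):
        return {"t": p.t, "n1": p.n1, "n2": p.n2}
    if isinstance(p, TwoSampleSummary):
        return {
            "n1": p.n1, "mean1": p.mean1, "sd1": p.sd1,
            "n2": p.n2, "mean2": p.mean2, "sd2": p.sd2,
        }
    if isinstance(p, CrossTable):
        return {
            "counts": [list(row) for row in p.counts],
            "row_labels": list(p.row_labels),
            "col_labels": list(p.col_labels),
            "fixed_margin": p.fixed_margin,
        }
    raise TypeError(f"unserializable payload {type(p).__name__}")


def record_to_dict(rec: StudyRecord) -> dict:
    d = {"design": rec.design, "role": rec.role, "label": rec.label}
    d.update(_payload_to_dict(rec))
    return d


def record_from_dict(d: dict, index: int = 0) -> StudyRecord:
    try:
        design = d["design"]
        role = d.get("role", "original")
        label = d.get("label", f"study-{index + 1}")
        if design == "binomial":
            payload = BinomialCount(int(d["successes"]), int(d["trials"]))
        elif design == "ttest":
            if "t" in d and d["t"] not in ("", None):
                payload = TStatSummary(float(d["t"]), int(d["n1"]), int(d["n2"]))
            else:
                payload = TwoSampleSummary(
                    int(d["n1"]), float(d["mean1"]), float(d["sd1"]),
                    int(d["n2"]), float(d["mean2"]), float(d["sd2"]),
                )
        elif design == "contingency":
            counts = d.get("counts")
            if counts is None:
                counts = [[int(d["c11"]), int(d["c12"])], [int(d["c21"]), int(d["c22"])]]
            payload = CrossTable(
                counts=tuple(tuple(int(v) for v in row) for row in counts),
                row_labels=tuple(d.get("row_labels", ("row1", "row2"))),
                col_labels=tuple(d.get("col_labels", ("col1", "col2"))),
                fixed_margin=d.get("fixed_margin", "rows"),
            )
        else:
            raise ValueError(f"unknown design {design!r}")
        return StudyRecord(design=design, role=role, payload=payload, label=label)
    except (KeyError, ValueError, TypeError) as exc:
        raise ValueError(f"record {index}: {exc}") from exc


_CSV_FIELDS = [
    "design", "role", "label",
    "successes", "trials",
    "t", "n1", "mean1", "sd1", "n2", "mean2", "sd2",
    "c11", "c12", "c21", "c22",
]


def read_studies(path: str | Path, format: str | None = None) -> list[StudyRecord]:
    """Read study records from a JSON or CSV file (format inferred from suffix).

    JSON: either a list of record objects or ``{"studies": [...]}``.
    CSV: one record per row with a header; unused design columns left blank.
    An empty file or empty record list is an error, not an empty result.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "json"
    if format not in ("json", "csv"):
        raise ValueError(f"unknown format {format!r}")
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: file is empty")
    if format == "json":
        raw = json.loads(text)
        if isinstance(raw, dict):
            raw = raw.get("studies", [])
        records = [record_from_dict(d, i) for i, d in enumerate(raw)]
    else:
        rows = [
            {k: v for k, v in row.items() if v not in ("", None)}
            for row in csv.DictReader(text.splitlines())
        ]
        records = [record_from_dict(d, i) for i, d in enumerate(rows)]
    if not records:
        raise ValueError(f"{path}: no study records found")
    return records


def write_studies(records: list[StudyRecord], path: str | Path, format: str | None = None) -> None:
    """Write records to JSON or CSV so that ``read_studies`` round-trips them."""
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "json"
    if format == "json":
        path.write_text(
            json.dumps({"studies": [record_to_dict(r) for r in records]}, indent=2) + "\n"
        )
    elif format == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=_CSV_FIELDS, extrasaction="ignore")
            writer.writeheader()
            for r in records:
                d = record_to_dict(r)
                if r.design == "contingency":
                    c = r.payload.counts
                    d.update(c11=c[0][0], c12=c[0][1], c21=c[1][0], c22=c[1][1])
                writer.writerow(d)
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# report generation


def _round_floats(obj, ndigits: int):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def _original_direction_binomial(data: BinomialCount, theta0: float) -> str:
    return "greater" if data.successes / data.trials >= theta0 else "less"


def run_replication_report(studies: list[StudyRecord], config: ReportConfig | None = None) -> dict:
    """Analyze an ordered original/replication record series into a report dict.

    The report carries per-study BFs, the complete (pooled-data) BF, the
    replication BF in both directions (and its order-restricted variant when
    the policy asks for one), prior descriptors, posterior credible-interval
    summaries for the binomial design, and the classical parity statistic.
    All numbers are kept at full precision; :func:`render_report_text`
    applies the configured rounding.
    """
    if config is None:
        config = ReportConfig()
    if not studies:
        raise ValueError("no study records supplied")
    design = studies[0].design
    if any(r.design != design for r in studies):
        raise ValueError("mixed designs in one report are not supported")
    combined = [r for r in studies if r.role == "combined"]
    ordered = [r for r in studies if r.role != "combined"]
    if not any(r.role == "original" for r in ordered):
        raise ValueError("at least one record with role 'original' is required")
    has_replication = any(r.role == "replication" for r in ordered)

    report: dict = {
        "design": design,
        "direction_policy": config.direction_policy,
        "studies": [],
    }

    if design == "binomial":
        _report_binomial(ordered, config, report)
    elif design == "ttest":
        _report_ttest(ordered, combined, config, report)
    else:
        _report_contingency(ordered, config, report)

    if not has_replication:
        report["replication"] = None
        report["note"] = "single original study: ordinary Bayes factor only"
    logger.info(
        "report design=%s studies=%d complete_bf10=%s replication=%s",
        design,
        len(ordered),
        report["complete"]["bf10"],
        (report["replication"] or {}).get("bf10") if report["replication"] else None,
    )
    return report


def _bf_entry(res) -> dict:
    return res.to_dict()


def _report_binomial(ordered, config: ReportConfig, report: dict) -> None:
    counts = [r.payload for r in ordered]
    chain = core.chain_evidence(counts, "binomial", prior=config.beta_prior, theta0=config.theta0)
    prior = config.beta_prior
    running = prior
    for rec, seq in zip(ordered, chain.sequential_bfs):
        running = update_beta(running, rec.payload)
        lo, hi = beta_credible_interval(running, config.credible_level)
        report["studies"].append(
            {
                "label": rec.label,
                "role": rec.role,
                "data": _payload_to_dict(rec),
                "bf10_sequential": seq,
                "posterior": {"alpha": running.alpha, "beta": running.beta},
                "credible_interval": {
                    "level": config.credible_level, "lower": lo, "upper": hi,
                },
            }
        )
    report["prior"] = {"family": "beta", "alpha": prior.alpha, "beta": prior.beta,
                       "theta0": config.theta0}
    report["complete"] = _bf_entry(chain.complete_bf)
    pooled = counts[0]
    for c in counts[1:]:
        pooled = pooled + c
    report["parity"] = {
        "test": "exact two-sided binomial",
        "p_value": binomial_two_sided_p(counts[0], config.theta0),
        "p_value_pooled": binomial_two_sided_p(pooled, config.theta0),
    }
    if len(counts) >= 2:
        rep_bf = chain.replication_bf()
        entry = {"bf10": rep_bf, "bf01": 1.0 / rep_bf, "kind": "two_sided"}
        if config.direction_policy == "order_restricted_by_original":
            direction = _original_direction_binomial(counts[0], config.theta0)
            orig = bf10_binomial_onesided(counts[0], prior, config.theta0, direction)
            complete = bf10_binomial_onesided(pooled, prior, config.theta0, direction)
            one_sided = core.replication_bf(complete.bf10, orig.bf10)
            entry.update(
                kind="order_restricted_by_original",
                direction=direction,
                bf10_order_restricted=one_sided,
                bf01_order_restricted=1.0 / one_sided,
            )
        report["replication"] = entry
    else:
        report["replication"] = None


def _report_ttest(ordered, combined, config: ReportConfig, report: dict) -> None:
    prior = config.effect_prior
    payloads = [r.payload for r in ordered]
    summaries_only = all(isinstance(p, TwoSampleSummary) for p in payloads)

    per_study = []
    for rec in ordered:
        p = rec.payload
        tstat = t_from_summaries(p) if isinstance(p, TwoSampleSummary) else p
        res = bf10_ttest(tstat, prior)
        per_study.append((rec, tstat, res))
        report["studies"].append(
            {
                "label": rec.label,
                "role": rec.role,
                "data": _payload_to_dict(rec),
                "t": tstat.t,
                "df": tstat.df,
                "bf10": res.bf10,
                "bf01": res.bf01,
            }
        )
    report["prior"] = {
        "family": prior.family, "location": prior.location, "scale": prior.scale,
        "truncation": prior.truncation,
    }

    if summaries_only:
        chain = core.chain_evidence(payloads, "ttest", prior=prior)
        complete = chain.complete_bf
        pooled = payloads[0]
        for p in payloads[1:]:
            pooled = pool_two_sample_summaries(pooled, p)
        pooled_t = t_from_summaries(pooled)
    elif combined:
        pooled_t = combined[0].payload
        if isinstance(pooled_t, TwoSampleSummary):
            pooled_t = t_from_summaries(pooled_t)
        complete = bf10_ttest(pooled_t, prior)
    elif len(ordered) == 1:
        pooled_t = per_study[0][1]
        complete = per_study[0][2]
    else:
        raise ValueError(
            "t-statistic payloads cannot be pooled from summaries; supply a "
            "role='combined' record with the pooled t, or full group summaries"
        )
    report["pooled_t"] = {"t": pooled_t.t, "n1": pooled_t.n1, "n2": pooled_t.n2, "df": pooled_t.df}
    report["complete"] = _bf_entry(complete)
    report["parity"] = {"test": "pooled-data t statistic", "t": pooled_t.t, "df": pooled_t.df}

    if len(ordered) >= 2:
        orig_res = per_study[0][2]
        rep_bf = core.replication_bf(complete.bf10, orig_res.bf10)
        entry = {"bf10": rep_bf, "bf01": 1.0 / rep_bf, "kind": "two_sided"}
        if config.direction_policy == "order_restricted_by_original":
            direction = "positive" if per_study[0][1].t >= 0 else "negative"
            trunc_prior = EffectSizePrior(
                family=prior.family, location=prior.location, scale=prior.scale,
                df=prior.df, truncation=direction,
            )
            orig_os = bf10_ttest_onesided(per_study[0][1], trunc_prior)
            complete_os = bf10_ttest_onesided(pooled_t, trunc_prior)
            one_sided = core.replication_bf(complete_os.bf10, orig_os.bf10)
            entry.update(
                kind="order_restricted_by_original",
                direction=direction,
                bf10_order_restricted=one_sided,
                bf01_order_restricted=1.0 / one_sided,
            )
        report["replication"] = entry
    else:
        report["replication"] = None


def _report_contingency(ordered, config: ReportConfig, report: dict) -> None:
    if config.direction_policy == "order_restricted_by_original":
        raise ValueError("order restriction is not available for the contingency design")
    prior = config.dirichlet_prior
    tables = [r.payload for r in ordered]
    chain = core.chain_evidence(tables, "contingency", prior=prior)
    for rec, seq in zip(ordered, chain.sequential_bfs):
        res = bf10_contingency(rec.payload, prior)
        stat, dof = pearson_chi_square(rec.payload)
        report["studies"].append(
            {
                "label": rec.label,
                "role": rec.role,
                "data": _payload_to_dict(rec),
                "bf10": res.bf10,
                "bf10_sequential": seq,
                "chi_square": {"statistic": stat, "df": dof, "n": rec.payload.total},
            }
        )
    report["prior"] = {"family": "dirichlet", "concentration": prior.concentration}
    report["complete"] = _bf_entry(chain.complete_bf)
    pooled = tables[0]
    for t in tables[1:]:
        pooled = pool_tables(pooled, t)
    stat, dof = pearson_chi_square(pooled)
    report["parity"] = {
        "test": "Pearson chi-square (pooled)", "statistic": stat, "df": dof, "n": pooled.total,
    }
    if len(tables) >= 2:
        rep_bf = chain.replication_bf()
        report["replication"] = {"bf10": rep_bf, "bf01": 1.0 / rep_bf, "kind": "two_sided"}
    else:
        report["replication"] = None


def render_report_text(report: dict, rounding: int = 3) -> str:
    """Human-readable text block; numbers match the JSON at the given rounding."""
    r = _round_floats(report, rounding)
    lines = [f"Replication report — design: {r['design']}"]
    for s in r["studies"]:
        bf = s.get("bf10", s.get("bf10_sequential"))
        lines.append(f"  [{s['role']}] {s['label']}: BF10 = {bf}")
        if "credible_interval" in s:
            ci = s["credible_interval"]
            lines.append(
                f"    {int(ci['level'] * 100)}% credible interval: "
                f"({ci['lower']}, {ci['upper']})"
            )
    lines.append(f"  complete BF10 = {r['complete']['bf10']} "
                 f"(BF01 = {r['complete']['bf01']})")
    if r.get("replication"):
        rep = r["replication"]
        lines.append(f"  replication BF10 = {rep['bf10']} (BF01 = {rep['bf01']})")
        if "bf10_order_restricted" in rep:
            lines.append(
                f"  order-restricted ({rep['direction']}) replication BF10 = "
                f"{rep['bf10_order_restricted']}"
            )
    else:
        lines.append("  replication BF: not applicable (single study)")
    return "\n".join(lines)


def report_to_json(report: dict, rounding: int | None = None) -> str:
    """Serialize a report; optional rounding for display parity with the text."""
    obj = report if rounding is None else _round_floats(report, rounding)
    return json.dumps(obj, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# synthetic study-series generators


def generate_binomial_series(
    theta_true: float,
    n_per_study: int,
    k_studies: int,
    seed: int,
) -> list[StudyRecord]:
    """Draw k independent binomial studies with true rate ``theta_true``."""
    if not (0.0 <= theta_true <= 1.0):
        raise ValueError("theta_true must lie in [0, 1]")
    if n_per_study < 1 or k_studies < 1:
        raise ValueError("n_per_study and k_studies must be positive")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(k_studies):
        k = int(rng.binomial(n_per_study, theta_true))
        records.append(
            StudyRecord(
                design="binomial",
                role="original" if i == 0 else "replication",
                payload=BinomialCount(k, n_per_study),
                label=f"sim-binomial-{i + 1}",
            )
        )
    logger.info("generated %d binomial studies (theta=%g, n=%d, seed=%d)",
                k_studies, theta_true, n_per_study, seed)
    return records


def generate_ttest_series(
    delta_true: float,
    n_per_group: int,
    k_studies: int,
    seed: int,
    shift_sd: float = 0.0,
) -> list[StudyRecord]:
    """Draw k two-group studies with standardized mean difference ``delta_true``.

    Observations are unit-variance normal; group 1 has mean delta_true above
    group 2.  ``shift_sd`` adds a per-study location shift (common to both
    groups, drawn from N(0, shift_sd^2)) emulating a nuisance-parameter
    change between studies — the failure mode that distorts pooled analyses.
    """
    if n_per_group < 2 or k_studies < 1:
        raise ValueError("need n_per_group >= 2 and k_studies >= 1")
    if shift_sd < 0:
        raise ValueError("shift_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(k_studies):
        shift = rng.normal(0.0, shift_sd) if shift_sd > 0 else 0.0
        g1 = rng.normal(delta_true + shift, 1.0, size=n_per_group)
        g2 = rng.normal(shift, 1.0, size=n_per_group)
        payload = TwoSampleSummary(
            n1=n_per_group, mean1=float(g1.mean()), sd1=float(g1.std(ddof=1)),
            n2=n_per_group, mean2=float(g2.mean()), sd2=float(g2.std(ddof=1)),
        )
        records.append(
            StudyRecord(
                design="ttest",
                role="original" if i == 0 else "replication",
                payload=payload,
                label=f"sim-ttest-{i + 1}",
            )
        )
    logger.info("generated %d t-test studies (delta=%g, n=%d, shift_sd=%g, seed=%d)",
                k_studies, delta_true, n_per_group, shift_sd, seed)
    return records
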