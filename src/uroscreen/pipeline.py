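"""End-to-end orchestration: screening table, flag agreement, angle rule.

``run_pipeline`` strings the three analysis stages together on a joined
cohort, writes every table as CSV (plus a Markdown report re-rendering the
same numbers — nothing appears in the report that is not in a CSV), and is
deterministic given its inputs. Stages degrade gracefully: if the channel
columns are absent the Gram-angle stage is skipped with a notice.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import agreement, gram, screening
from .io import JoinedCohort, join_cohort, read_cultures, read_samples
from .records import CfuCategory, Cohort, CultureStatus, Gram
from ._util import frame_to_markdown, round_half_up

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "threshold_table_frame"]

DEFAULT_TARGETS = (80.0, 85.0, 90.0, 95.0, 97.5, 99.0)


@dataclass
class RunConfig:
    samples_path: Path
    cultures_path: Path
    out_dir: Path
    positivity: str = "1e4"  # "1e4" or "1e5"
    bact_cutoff: float = gram.DEFAULT_BACT_CUTOFF
    targets: Sequence[float] = DEFAULT_TARGETS
    collapsing: str = "three_class"
    angle_cutoff: float = 28.0
    seed: int = 0

    def validate(self) -> None:
        if self.positivity not in ("1e4", "1e5"):
            raise ValueError(f"positivity must be '1e4' or '1e5', got {self.positivity!r}")
        if self.collapsing not in agreement.COLLAPSING_SCHEMES:
            raise ValueError(f"unknown collapsing scheme {self.collapsing!r}")
        if not (0 <= self.angle_cutoff < 90):
            raise ValueError(f"angle_cutoff must lie in [0, 90), got {self.angle_cutoff!r}")


def _positive_label(culture, positivity: str) -> int:
    if culture.status is not CultureStatus.POSITIVE:
        return 0
    if positivity == "1e5":
        return int(culture.cfu_category is CfuCategory.GE_1E5)
    return 1


def threshold_table_frame(rows: list[screening.ThresholdRow]):
    """Cut-off table in the conventional screening-report layout."""
    import pandas as pd

    recs = []
    for r in rows:
        m = r.metrics.rounded()
        recs.append(
            {
                "nominal_sen_pct": r.nominal_sensitivity,
                "cutoff_per_ul": r.cutoff,
                "sen_pct": m["sensitivity"],
                "spe_pct": m["specificity"],
                "ppv_pct": m["ppv"],
                "npv_pct": m["npv"],
                "tp": r.counts.tp,
                "fn": r.counts.fn,
                "tn": r.counts.tn,
                "fp": r.counts.fp,
            }
        )
    return pd.DataFrame(recs)


def run_pipeline(config: RunConfig) -> dict:
    """Run screening -> agreement -> angle stages; write the report bundle.

    Returns the metrics dictionary that is also written to metrics.json.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    samples = read_samples(config.samples_path)
    cultures = read_cultures(config.cultures_path)
    joined = join_cohort(samples, cultures)

    metrics: dict = {"config": {
        "positivity": config.positivity,
        "bact_cutoff": config.bact_cutoff,
        "targets": list(config.targets),
        "collapsing": config.collapsing,
        "angle_cutoff": config.angle_cutoff,
        "seed": config.seed,
    }, "cohort": {
        "n_joined": len(joined.pairs),
        "n_bacterial": len(joined.bacterial),
        "n_yeast_excluded": joined.n_yeast_excluded,
        "n_contaminated_excluded": joined.n_contaminated_excluded,
    }}
    report_lines = [
        "# UF-5000 screening report",
        "",
        f"- specimens joined: {len(joined.pairs)}",
        f"- bacterial-analysis denominator: {len(joined.bacterial)} "
        f"(excluded {joined.n_yeast_excluded} yeast, "
        f"{joined.n_contaminated_excluded} contaminated)",
        f"- culture positivity criterion: >=10^{config.positivity[-1]} CFU/mL",
        "",
    ]

    # --- stage 1: screening ------------------------------------------------
    try:
        bact = np.array([s.bact_per_ul for s, _ in joined.bacterial])
        labels = np.array([_positive_label(c, config.positivity) for _, c in joined.bacterial])
        roc = screening.empirical_roc(bact, labels)
        ci = screening.auc_ci(bact, labels)
        rows = screening.sensitivity_table(bact, labels, config.targets)
        tbl = threshold_table_frame(rows)
        tbl.to_csv(out / "screening_table.csv", index=False, lineterminator="\n")

        wl_rows = []
        for r in rows:
            wl = screening.workload_reduction(r.counts)
            red, fnr = wl.rounded()
            wl_rows.append({"nominal_sen_pct": r.nominal_sensitivity,
                            "culture_reduction_pct": red,
                            "false_negative_rate_pct": fnr})
        metrics["screening"] = {
            "auc": round_half_up(roc.auc, 3),
            "auc_ci95": [round_half_up(ci[0], 3), round_half_up(ci[1], 3)],
            "rows": tbl.to_dict(orient="records"),
            "workload": wl_rows,
        }
        report_lines += [
            "## Screening (BACT vs culture)",
            "",
            f"AUC {round_half_up(roc.auc, 3)} "
            f"(95% CI {round_half_up(ci[0], 3)} to {round_half_up(ci[1], 3)})",
            "",
            frame_to_markdown(tbl),
            "",
        ]
    except Exception as exc:
        raise RuntimeError(f"screening stage failed: {exc}") from exc

    # --- stage 2: flag agreement ------------------------------------------
    try:
        flags = [s.flag for s, _ in joined.bacterial]
        classes = [c.culture_class() for _, c in joined.bacterial]
        tab = agreement.crosstab(flags, classes, bact=bact, bact_cutoff=config.bact_cutoff)
        tab.with_margins().to_csv(out / "agreement_table.csv", lineterminator="\n")
        kappa = agreement.cohen_kappa(tab, config.collapsing)
        gn = agreement.gram_flag_metrics(tab, "GN")
        gp = agreement.gram_flag_metrics(tab, "GP")
        kappa_payload = {
            "kappa": None if kappa.kappa is None else round_half_up(kappa.kappa, 3),
            "observed_agreement": round_half_up(kappa.observed_agreement, 3),
            "expected_agreement": round_half_up(kappa.expected_agreement, 3),
            "collapsing": kappa.collapsing,
        }
        (out / "kappa.json").write_text(json.dumps(kappa_payload, indent=2) + "\n")
        metrics["agreement"] = {
            **kappa_payload,
            "n_included": tab.total,
            "gn_flag": gn.rounded(),
            "gp_flag": gp.rounded(),
        }
        report_lines += [
            f"## Flag agreement (BACT >= {config.bact_cutoff}/µL, n={tab.total})",
            "",
            frame_to_markdown(tab.with_margins(), index=True),
            "",
            f"Cohen's kappa ({kappa.collapsing}): {kappa_payload['kappa']} "
            f"(Po {kappa_payload['observed_agreement']}, Pe {kappa_payload['expected_agreement']})",
            f"GN flag: PPV {gn.rounded()['ppv']}%, specificity {gn.rounded()['specificity']}%",
            f"GP flag: PPV {gp.rounded()['ppv']}%",
            "",
        ]
    except Exception as exc:
        raise RuntimeError(f"flag-agreement stage failed: {exc}") from exc

    # --- stage 3: gram angle ----------------------------------------------
    have_channels = all(
        s.b_fsc_ch is not None and s.b_flh_ch is not None for s, _ in joined.bacterial
    )
    gram_pairs = [
        (s, c) for s, c in joined.bacterial
        if c.status is CultureStatus.POSITIVE
    ]
    if not have_channels or not gram_pairs:
        metrics["gram_angle"] = {"skipped": True,
                                 "reason": "missing channel values" if not have_channels else "no positives"}
        report_lines += ["## Gram angle", "", "_Stage skipped: "
                         + metrics["gram_angle"]["reason"] + "._", ""]
    else:
        try:
            train = [(s, c) for s, c in gram_pairs if s.cohort is Cohort.TRAINING]
            valid = [(s, c) for s, c in gram_pairs if s.cohort is Cohort.VALIDATION]
            fitted = None
            if train:
                ratios = [gram.fsc_flh_ratio(s.b_fsc_ch, s.b_flh_ch) for s, _ in train]
                glabels = ["GN" if Gram.NEGATIVE in c.gram_classes else "GP" for _, c in train]
                if len(set(glabels)) == 2:
                    fitted = gram.fit_ratio_cutoff(ratios, glabels)
            eval_pairs = valid or gram_pairs
            ev_samples = [s for s, _ in eval_pairs]
            ev_labels = ["GN" if Gram.NEGATIVE in c.gram_classes else "GP" for _, c in eval_pairs]
            preds, counts, skipped = gram.classify_by_angle(
                ev_samples, config.angle_cutoff, ev_labels, bact_cutoff=config.bact_cutoff
            )
            m = screening.diagnostic_metrics(counts).rounded() if counts else {}
            metrics["gram_angle"] = {
                "skipped": False,
                "fitted_ratio_cutoff": None if fitted is None else round_half_up(fitted.ratio_cutoff, 3),
                "fitted_angle_deg": None if fitted is None else fitted.angle_cutoff_deg,
                "applied_angle_deg": config.angle_cutoff,
                "validation_counts": {"tp": counts.tp, "fn": counts.fn,
                                      "tn": counts.tn, "fp": counts.fp},
                "validation_metrics": m,
                "n_skipped_missing_channels": skipped,
            }
            import pandas as pd

            pd.DataFrame({
                "sample_id": [s.sample_id for s in ev_samples],
                "prediction": preds,
                "culture_gram": ev_labels,
            }).to_csv(out / "gram_predictions.csv", index=False, lineterminator="\n")
            report_lines += [
                "## Gram angle rule",
                "",
                (f"Fitted ratio cut-off {metrics['gram_angle']['fitted_ratio_cutoff']} "
                 f"(angle {metrics['gram_angle']['fitted_angle_deg']}°). " if fitted else "")
                + f"Applied angle {config.angle_cutoff}°: "
                  f"TP {counts.tp}, FN {counts.fn}, TN {counts.tn}, FP {counts.fp}; "
                  f"PPV for GN {m.get('ppv')}%",
                "",
            ]
        except Exception as exc:
            raise RuntimeError(f"gram-angle stage failed: {exc}") from exc

    (out / "metrics.json").write_text(json.dumps(metrics, indent=2) + "\n")
    (out / "report.md").write_text("\n".join(report_lines) + "\n")
    return metrics


def plot_scattergram(samples, gram_labels, angle_cutoff_deg: float, path) -> None:
    """Scatter B_FLH (x) vs B_FSC (y) coloured by Gram class, with the
    cut-off ray drawn from the origin."""
    import matplotlib

    matplotlib.use("Agg")
    import math

    import matplotlib.pyplot as plt

    fsc = np.array([s.b_fsc_ch for s in samples], dtype=float)
    flh = np.array([s.b_flh_ch for s in samples], dtype=float)
    y = gram._as_gn_indicator(gram_labels)

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(flh[y == 1], fsc[y == 1], s=12, alpha=0.6, label="Gram-negative")
    ax.scatter(flh[y == 0], fsc[y == 0], s=12, alpha=0.6, label="Gram-positive")
    xmax = float(flh.max()) * 1.05
    slope = math.tan(math.radians(angle_cutoff_deg))
    ax.plot([0, xmax], [0, xmax * slope], "k--", label=f"{angle_cutoff_deg}° cut-off")
    ax.set_xlabel("B_FLH (ch)")
    ax.set_ylabel("B_FSC (ch)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
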