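"""Post-processing: plateau tables, model-comparison fold-changes,
report serialisation and figure regeneration.

``summarize_timecourse`` and ``compare_models`` both defer to
:func:`brainenergy.simulator.detect_steady_state` as the single source
of truth for plateau values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .simulator import TimeCourse, detect_steady_state

__all__ = [
    "ComparisonReport",
    "summarize_timecourse",
    "compare_models",
    "write_report",
    "read_report",
    "plot_panels",
]

#: the series the study reports on (neuron mitochondrial ATP is the
#: headline comparison axis)
DEFAULT_SPECIES = ("ATP@Nm", "ATP@Nc", "ATP@Ac", "Lac@e", "Lac@Nc", "Lac@Ac", "Glc@b")


def summarize_timecourse(
    tc: TimeCourse,
    species: Sequence[str] = DEFAULT_SPECIES,
    window: float = 30.0,
    rel_tol: float = 0.01,
) -> pd.DataFrame:
    """Plateau value + attainment time per requested series.

    Not-attained series carry their final value with ``attained=False``.
    Unknown species keys raise ``KeyError``.
    """
    if len(tc.data) == 0:
        raise ValueError("empty time course")
    rows = []
    for key in species:
        rep = detect_steady_state(tc, key, window=window, rel_tol=rel_tol)
        rows.append(
            dict(
                species=key,
                plateau_mM=rep.plateau,
                attained=rep.attained,
                attainment_time_min=rep.attainment_time,
            )
        )
    return pd.DataFrame(rows).set_index("species")


@dataclass
class ComparisonReport:
    """Classical-vs-ANLSH plateau fold-changes per scenario.

    ``table`` rows are (species, scenario) pairs with both plateaus, the
    anlsh/classical fold-change (NaN where the classical plateau is not
    positive) and both attainment times.  ``mean_fold_change`` averages
    the fold-change across scenarios per species.
    """

    table: pd.DataFrame
    mean_fold_change: dict[str, float]
    parameter_digest: str | None = None
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "schema": "brainenergy.comparison/1",
            "parameter_digest": self.parameter_digest,
            "metadata": self.metadata,
            "mean_fold_change": self.mean_fold_change,
            "rows": self.table.reset_index(drop=True).to_dict(orient="records"),
        }


def _scenario_signature(tc: TimeCourse) -> tuple:
    m = tc.metadata
    return (
        m.get("scenario"),
        m.get("blood_glucose_mM"),
        m.get("blood_o2_mM"),
        m.get("blood_glucose_clamped"),
    )


def compare_models(
    experiments: Mapping[tuple[str, str], TimeCourse],
    species: Sequence[str] = ("ATP@Nm",),
    window: float = 30.0,
    rel_tol: float = 0.01,
) -> ComparisonReport:
    """Pair (classical, anlsh) runs scenario-by-scenario and compute
    plateau fold-changes.

    ``experiments`` maps (variant, scenario name) to a time course; both
    variants must be present for every scenario, with matching scenario
    definitions, or a ``ValueError`` is raised.
    """
    scenarios = sorted({k[1] for k in experiments})
    rows = []
    for sc in scenarios:
        try:
            tc_c = experiments[("classical", sc)]
            tc_a = experiments[("anlsh", sc)]
        except KeyError as exc:
            raise ValueError(f"scenario {sc!r} missing variant {exc}") from None
        if _scenario_signature(tc_c) != _scenario_signature(tc_a):
            raise ValueError(
                f"scenario {sc!r}: the two variants were run under different "
                f"boundary conditions"
            )
        for key in species:
            rc = detect_steady_state(tc_c, key, window=window, rel_tol=rel_tol)
            ra = detect_steady_state(tc_a, key, window=window, rel_tol=rel_tol)
            fold = (
                ra.plateau / rc.plateau
                if rc.plateau is not None and rc.plateau > 0
                else float("nan")
            )
            rows.append(
                dict(
                    species=key,
                    scenario=sc,
                    classical_plateau_mM=rc.plateau,
                    anlsh_plateau_mM=ra.plateau,
                    fold_change=fold,
                    classical_attainment_min=rc.attainment_time,
                    anlsh_attainment_min=ra.attainment_time,
                )
            )
    table = pd.DataFrame(rows)
    mean_fold = (
        table.dropna(subset=["fold_change"])
        .groupby("species")["fold_change"]
        .mean()
        .to_dict()
    )
    digest = next(
        (tc.metadata.get("parameter_digest") for tc in experiments.values()), None
    )
    return ComparisonReport(table, mean_fold, digest)


def write_report(report: ComparisonReport | pd.DataFrame, path, format: str = "json"):
    """Lossless serialisation of a comparison report or plateau table."""
    if format == "json":
        if isinstance(report, pd.DataFrame):
            doc = {
                "schema": "brainenergy.table/1",
                "rows": report.reset_index().to_dict(orient="records"),
            }
        else:
            doc = report.to_dict()
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")
    elif format == "csv":
        table = report if isinstance(report, pd.DataFrame) else report.table
        table.to_csv(path, index=isinstance(report, pd.DataFrame))
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def plot_panels(
    timecourses: Mapping[str, TimeCourse],
    keys: Sequence[str],
    path=None,
    title: str | None = None,
):
    """Regenerate the study's panel layout: one subplot per species key,
    one line per labelled time course.  Returns the matplotlib figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ncol = 2
    nrow = (len(keys) + ncol - 1) // ncol
    fig, axes = plt.subplots(nrow, ncol, figsize=(9, 3 * nrow), squeeze=False)
    for ax, key in zip(axes.flat, keys):
        for label, tc in timecourses.items():
            ax.plot(tc.times, tc.series(key), label=label)
        ax.set_xlabel("time (min)")
        ax.set_ylabel(f"{key} (mM)")
        ax.legend(fontsize=7)
    for ax in axes.flat[len(keys):]:
        ax.axis("off")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
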