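"""End-to-end pipeline: simulate/read records -> PDC panel -> trajectory fit
-> selection + adequacy -> predictor tables -> figure data, with a manifest
recording the seed and a config hash so a run is fully reproducible."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gbtm, pdc, predictors, selection, synthetic

log = logging.getLogger("adhertraj")


@dataclass
class RunConfig:
    """Every knob of an end-to-end run; serialising this fixes the outputs."""

    seed: int = 42
    simulate: bool = True
    n_patients: int = 350
    records_csv: str | None = None
    covariates_csv: str | None = None
    window_start: str = "2022-01-01"
    n_periods: int = 12
    period_length_days: int = 30
    threshold: float = 0.8
    groups: list[int] = field(default_factory=lambda: [2, 3, 4, 5])
    orders: list[int] = field(default_factory=lambda: [2])
    n_starts: int = 20
    min_prop: float = 0.05
    group_labels: list[str] | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def export_figure_data(
    model: gbtm.TrajectoryModel,
    panel: np.ndarray,
    assignments: np.ndarray,
) -> pd.DataFrame:
    """Long-format plotting contract: (group, period, predicted, observed).

    Predicted values come from the fitted curves, observed from per-group
    adherence proportions at each period — the solid/dotted line pair of the
    standard trajectory plot.
    """
    T = panel.shape[1]
    t = np.arange(1, T + 1)
    obs = gbtm.observed_curve(panel, assignments, model.n_groups)
    rows = []
    for g in range(model.n_groups):
        pred = gbtm.predicted_curve(model, g, t)
        for j in range(T):
            rows.append(
                {
                    "group": g,
                    "period": int(t[j]),
                    "predicted": float(pred[j]),
                    "observed": float(obs[g, j]),
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run every stage and write the artifact bundle under ``outdir``.

    Returns a dict with the in-memory results and the path of each artifact.
    Any stage failure propagates with the stage named in the message.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    window_start = date.fromisoformat(config.window_start)
    artifacts: dict = {"outdir": outdir}

    # --- stage: records ----------------------------------------------------
    if config.simulate:
        spec = synthetic.CohortSpec(
            n_patients=config.n_patients,
            n_periods=config.n_periods,
            period_length_days=config.period_length_days,
            seed=config.seed,
        )
        cohort = synthetic.sample_cohort(spec)
        paths = cohort.write_csvs(outdir)
        records = cohort.records
        covariates = cohort.covariates
        patient_ids = cohort.patient_ids
        artifacts["cohort"] = cohort
        log.info("simulate: %d patients, %d dispensing records",
                 spec.n_patients, len(records))
    else:
        if not config.records_csv or not Path(config.records_csv).exists():
            raise FileNotFoundError(
                f"stage 'records': dispensing file not found: {config.records_csv}"
            )
        records = pdc.read_dispensing_csv(config.records_csv)
        patient_ids = sorted({r.patient_id for r in records})
        covariates = None
        if config.covariates_csv:
            covariates = pd.read_csv(config.covariates_csv, dtype={"patient_id": str})
            covariates = covariates.set_index("patient_id").loc[patient_ids].reset_index()
        log.info("read: %d dispensing records, %d patients",
                 len(records), len(patient_ids))

    # --- stage: pdc --------------------------------------------------------
    panels = pdc.build_panels(
        records, window_start, patient_ids,
        config.n_periods, config.period_length_days, config.threshold,
    )
    panel_frame = pdc.panels_to_frame(panels)
    panel_frame.to_csv(outdir / "panel.csv", index=False)
    panel = pdc.binary_matrix(panels)
    log.info("pdc: panel %d x %d, overall adherent %d",
             *panel.shape, int(sum(p.overall_binary for p in panels)))

    # --- stage: fit + select ----------------------------------------------
    grid = selection.fit_grid(
        panel, groups=config.groups, orders=config.orders,
        n_starts=config.n_starts, seed=config.seed,
    )
    model, trace = selection.select_model(grid, config.min_prop)
    trace.to_csv(outdir / "selection_trace.csv", index=False)
    model.to_json(outdir / "model.json")
    log.info("select: %d groups, order %d, BIC %.2f",
             model.n_groups, model.order, model.bic)

    # --- stage: posterior + adequacy ---------------------------------------
    post = gbtm.posterior(model, panel)
    assignments = gbtm.hard_assign(post)
    labels = _group_labels(config, model.n_groups)
    assign_frame = pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in panels],
            "assigned_group": assignments,
            "assigned_label": [labels[g] for g in assignments],
            **{f"posterior_{g}": post[:, g] for g in range(model.n_groups)},
        }
    )
    assign_frame.to_csv(outdir / "assignments.csv", index=False)
    adequacy = selection.adequacy_report(model, post, config.min_prop)
    adequacy.to_csv(outdir / "adequacy.csv", index=False)

    # --- stage: discordance ------------------------------------------------
    discordance = pdc.compare_classifications(panels, assignments, adherent_group=0)

    # --- stage: predictors -------------------------------------------------
    predictor_tables = {}
    if covariates is not None:
        label_map = dict(enumerate(labels))
        biv = predictors.bivariate_table(covariates, assignments, group_labels=label_map)
        biv.to_csv(outdir / "bivariate.csv", index=False)
        mnl = predictors.fit_multinomial(
            covariates, assignments, reference_group=0, group_labels=label_map
        )
        mnl.table.to_csv(outdir / "multinomial.csv", index=False)
        predictors.format_or_table(mnl).to_csv(outdir / "or_table.csv", index=False)
        predictor_tables = {"bivariate": biv, "multinomial": mnl}
        log.info("predictors: %d contrasts fitted", len(mnl.table))

    # --- stage: figure data -------------------------------------------------
    figure = export_figure_data(model, panel, assignments)
    figure.to_csv(outdir / "figure_data.csv", index=False)

    manifest = {
        "seed": config.seed,
        "config": config.to_dict(),
        "config_sha256": config.digest(),
        "n_patients": len(panels),
        "selected_groups": model.n_groups,
        "selected_order": model.order,
        "bic": model.bic,
        "discordance": {
            "n_both": discordance.n_both,
            "n_gbtm_only": discordance.n_gbtm_only,
            "n_binary_only": discordance.n_binary_only,
            "n_neither": discordance.n_neither,
            "gbtm_only_pdc_range": discordance.gbtm_only_pdc_range,
        },
        "artifacts": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    artifacts.update(
        panels=panels,
        panel=panel,
        model=model,
        trace=trace,
        posterior=post,
        assignments=assignments,
        adequacy=adequacy,
        discordance=discordance,
        predictors=predictor_tables,
        figure=figure,
        manifest=manifest,
    )
    return artifacts


def _group_labels(config: RunConfig, n_groups: int) -> list[str]:
    if config.group_labels:
        if len(config.group_labels) != n_groups:
            raise ValueError(
                f"{len(config.group_labels)} labels given for {n_groups} groups"
            )
        return list(config.group_labels)
    # canonical order is descending adherence, so group 0 is the adherent one
    return ["adherent"] + [f"group{g}" for g in range(1, n_groups)]


__all__ = ["RunConfig", "run_pipeline", "export_figure_data"]
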