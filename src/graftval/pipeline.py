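"""End-to-end study driver: exclusions -> features -> scores -> horizon
endpoints -> AUROC/DeLong comparison table -> KM by risk class -> risk-factor
tables.  Every artifact is a CSV (plus a JSON run log); the run is a pure
function of (inputs, config, seed)."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import discrimination, riskfactors, scores as sc, survival
from .cohort import Cohort, apply_exclusions, read_cohort, write_cohort
from .features import MODELS, features_table
from .synthetic import SyntheticConfig, generate_cohort

#: clinical covariates screened against the high-risk class (Table-2 shape)
DEFAULT_RISK_VARIABLES = [
    "recipient_age",
    "recipient_male",
    "recipient_bmi",
    "diagnosis",
    "meld",
    "preop_crea_umol_l",
    "preop_tbil_umol_l",
    "preop_inr",
    "child_pugh",
    "donor_age",
    "donor_male",
    "donor_bmi",
    "donation_category",
    "dri",
    "anhepatic_min",
    "cit_min",
    "operation_min",
    "rbc_units",
    "ffp_units",
    "hemorrhage_ml",
]

_GROUP_COLUMNS = {
    "lgraft7": "lgraft7_group",
    "lgraft10": "lgraft10_group",
    "meaf": "meaf_group",
    "ease": "ease_group",
    "ead": "ead",
}


@dataclass
class RunConfig:
    labs_path: str | None = None
    clinical_path: str | None = None
    simulate: SyntheticConfig | None = None
    out_dir: str = "results"
    seed: int = 0
    horizons: tuple[int, ...] = survival.HORIZONS
    endpoints: tuple[str, ...] = survival.ENDPOINTS
    censored_as_survivor: bool = False
    auc_normalized: bool = False
    screen_p: float = riskfactors.SCREEN_P
    models: tuple[str, ...] = MODELS
    risk_variables: list[str] = field(default_factory=lambda: list(DEFAULT_RISK_VARIABLES))

    def __post_init__(self) -> None:
        bad = set(self.horizons) - set(survival.HORIZONS)
        if bad:
            raise ValueError(f"unsupported horizons {sorted(bad)}; allowed {survival.HORIZONS}")
        if self.simulate is None and (self.labs_path is None or self.clinical_path is None):
            raise ValueError("either input paths or a simulate config is required")


def load_cohort(config: RunConfig) -> Cohort:
    if config.simulate is not None:
        return generate_cohort(config.simulate)
    return read_cohort(config.labs_path, config.clinical_path)


def scores_frame(cohort: Cohort, normalized: bool = False) -> pd.DataFrame:
    """One row per patient: the ``scores.csv`` layout, indexed by patient."""
    rows = [
        sc.panel_row(sc.score_panel(cohort.labs[pid], cohort.clinical[pid], normalized))
        for pid in cohort.patient_ids()
    ]
    return pd.DataFrame(rows).set_index("patient_id")


def validation_tables(
    cohort: Cohort,
    score_df: pd.DataFrame,
    config: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-horizon/endpoint AUROC table and pairwise DeLong p-values."""
    roc_rows, pair_rows = [], []
    model_cols = [m for m in config.models if m in score_df.columns]
    outcomes = [cohort.outcomes[pid] for pid in score_df.index]
    for horizon in config.horizons:
        for endpoint in config.endpoints:
            labels = survival.derive_labels(
                outcomes, horizon, endpoint, config.censored_as_survivor
            )
            label_series = pd.Series(
                {l.patient_id: l.label for l in labels}, name="label"
            ).loc[score_df.index]
            included = label_series[label_series != "excluded"]
            y = (included == "event").astype(int)
            if y.nunique() < 2:
                continue
            rocs, pairwise = discrimination.compare_all_models(
                score_df.loc[included.index, model_cols], y, model_cols
            )
            for model, roc in rocs.items():
                roc_rows.append(
                    {
                        "model": model,
                        "horizon_days": horizon,
                        "endpoint": endpoint,
                        "n_events": roc.n_events,
                        "n_survivors": roc.n_survivors,
                        "auroc": roc.auroc,
                        "ci_low": roc.ci_low,
                        "ci_high": roc.ci_high,
                    }
                )
            pairwise.insert(0, "horizon_days", horizon)
            pairwise.insert(1, "endpoint", endpoint)
            pair_rows.append(pairwise)
    roc_table = pd.DataFrame(roc_rows)
    pair_table = (
        pd.concat(pair_rows, ignore_index=True) if pair_rows else pd.DataFrame()
    )
    return roc_table, pair_table


def km_by_risk_class(
    cohort: Cohort, score_df: pd.DataFrame, models: tuple[str, ...]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Graft-survival KM tables per risk class and a log-rank test per model."""
    km_rows, lr_rows = [], []
    for model in models:
        col = _GROUP_COLUMNS.get(model)
        if col is None or col not in score_df.columns:
            continue
        groups = score_df[col].dropna()
        if groups.empty:
            continue
        samples = []
        for value in sorted(groups.unique()):
            ids = groups.index[groups == value]
            pairs = [
                survival.time_and_event(cohort.outcomes[pid], "graft") for pid in ids
            ]
            times = np.array([t for t, _ in pairs])
            events = np.array([int(e) for _, e in pairs])
            samples.append((value, times, events))
            curve = survival.km_estimate(times, events) if times.size else None
            if curve is not None and curve.times.size:
                table = survival.km_table(curve)
                table.insert(0, "model", model)
                table.insert(1, "risk_class", value)
                km_rows.append(table)
        if len(samples) >= 2:
            chi2, df, p = survival.logrank_test([(t, e) for _, t, e in samples])
            lr_rows.append(
                {"model": model, "n_classes": len(samples), "chi2": chi2, "df": df, "p": p}
            )
    km = pd.concat(km_rows, ignore_index=True) if km_rows else pd.DataFrame()
    return km, pd.DataFrame(lr_rows)


def clinical_frame(cohort: Cohort) -> pd.DataFrame:
    from dataclasses import asdict

    rows = [asdict(cohort.clinical[pid]) for pid in cohort.patient_ids()]
    df = pd.DataFrame(rows).set_index("patient_id")
    for col in ("recipient_male", "donor_male"):
        if col in df:
            df[col] = df[col].astype(float)
    return df


def run_study(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the artifact dict and writes every
    table under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort = load_cohort(config)
    if config.simulate is not None:
        write_cohort(cohort, out / "labs.csv", out / "clinical.csv")
        (out / "simulate_config.json").write_text(
            json.dumps(config.simulate.to_dict(), indent=2, sort_keys=True) + "\n"
        )

    eligible, tally = apply_exclusions(cohort)
    pd.DataFrame(
        [{"category": k, "excluded": v} for k, v in tally.items()]
    ).to_csv(out / "exclusions.csv", index=False)

    features_table(eligible, normalized=config.auc_normalized).to_csv(
        out / "features.csv", index=False
    )
    score_df = scores_frame(eligible, normalized=config.auc_normalized)
    score_df.to_csv(out / "scores.csv")

    roc_table, pair_table = validation_tables(eligible, score_df, config)
    roc_table.to_csv(out / "table1_auroc.csv", index=False)
    pair_table.to_csv(out / "table1_pairwise.csv", index=False)

    km, logrank = km_by_risk_class(eligible, score_df, config.models)
    km.to_csv(out / "km_by_risk_class.csv", index=False)
    logrank.to_csv(out / "logrank_by_model.csv", index=False)

    screen = retained = fit = None
    if "lgraft7_high" in score_df.columns and score_df["lgraft7_high"].notna().any():
        data = clinical_frame(eligible).join(score_df["lgraft7_high"]).dropna(
            subset=["lgraft7_high"]
        )
        variables = [v for v in config.risk_variables if v in data.columns]
        screen, retained, fit = riskfactors.screen_then_fit(
            data, "lgraft7_high", variables, screen_p=config.screen_p
        )
        screen.to_csv(out / "table2_univariable.csv", index=False)
        if fit is not None:
            fit.terms.to_csv(out / "table3_multivariable.csv", index=False)

    log = {
        "seed": config.seed,
        "n_input": len(cohort),
        "n_eligible": len(eligible),
        "exclusions": tally,
        "horizons": list(config.horizons),
        "endpoints": list(config.endpoints),
        "censored_as_survivor": config.censored_as_survivor,
        "auc_normalized": config.auc_normalized,
        "screen_p": config.screen_p,
        "models": list(config.models),
        "risk_factor_retained": retained,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    return {
        "cohort": eligible,
        "exclusions": tally,
        "scores": score_df,
        "table1": roc_table,
        "pairwise": pair_table,
        "km": km,
        "logrank": logrank,
        "screen": screen,
        "fit": fit,
    }
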