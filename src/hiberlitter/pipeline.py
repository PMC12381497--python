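"""One-command orchestration: simulate (or ingest) a cohort, then run
hibernation → nutrition → reproduction → stats and emit report tables.

Outputs are deterministic under a fixed config and seed: rerunning
``run_all`` with the same configuration produces byte-identical files and an
identical manifest.  The manifest records the config hash, seed, package
version and a checksum per output file; wall-clock timing goes only to the
run log, which is outside the determinism contract.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .hibernation import (
    detect_torpor_bouts,
    exclude_isolated_bouts,
    phenology_table,
    summarize_hibernation,
)
from .nutrition import compute_intake, preference_fraction, preference_test
from .reproduction import (
    assign_pups,
    daily_means,
    detect_parturitions,
    fit_growth_models,
    flag_certain_first_litter,
    growth_points,
    infer_birth_date,
    litter_table,
    season_mass,
)
from .stats_report import compare_groups, count_model, mixed_model, simple_regression
from .synthetic import DIET_CROPS, FOCAL_CROP, CohortConfig, emit_cohort
from .trace_io import (
    SchemaError,
    read_captures,
    read_crops,
    read_feeding,
    read_periods,
    read_traces,
    write_table,
)

__all__ = ["RunManifest", "StageError", "run_all"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    checksums: dict[str, str]
    record_counts: dict[str, int]

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "seed": self.seed,
                "version": self.version,
                "checksums": self.checksums,
                "record_counts": self.record_counts,
            },
            indent=2,
            sort_keys=True,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: CohortConfig) -> str:
    import dataclasses

    d = dataclasses.asdict(config)
    for k, v in d.items():
        if isinstance(v, date):
            d[k] = v.isoformat()
        elif isinstance(v, tuple):
            d[k] = list(v)
    return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()


def run_all(
    config: CohortConfig,
    out_dir,
    data_dir=None,
    threshold: float = 30.0,
    min_duration_h: float = 24.0,
    max_gap_days: float = 15.0,
    jump: float = 1.0,
    refractory: int = 18,
) -> RunManifest:
    """Run the full pipeline and write report tables under ``out_dir``.

    When ``data_dir`` is None a synthetic cohort is generated from ``config``
    into ``out_dir / "data"``; otherwise the observable CSVs are ingested
    from ``data_dir`` (truth files, if any, are ignored by the analysis).
    Stage failures raise :class:`StageError` naming the stage.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(stage: str, message: str) -> None:
        log_lines.append(f"[{time.strftime('%Y-%m-%dT%H:%M:%S')}] {stage}: {message}")

    # --- stage: data ------------------------------------------------------
    try:
        if data_dir is None:
            data_paths, _truth = emit_cohort(config, out_dir / "data")
            data_dir = out_dir / "data"
        else:
            data_dir = Path(data_dir)
            data_paths = {
                "traces_winter": data_dir / "traces_winter.csv",
                "traces_reproduction": data_dir / "traces_reproduction.csv",
                "captures": data_dir / "captures.csv",
                "feeding": data_dir / "feeding.csv",
                "crops": data_dir / "crops.csv",
                "periods": data_dir / "periods.csv",
            }
        for key in ("traces_winter", "traces_reproduction", "captures", "feeding", "crops", "periods"):
            if not Path(data_paths[key]).exists():
                raise SchemaError(f"required input file {data_paths[key]} not found")
        winter_traces = read_traces(data_paths["traces_winter"])
        repro_traces = read_traces(data_paths["traces_reproduction"])
        captures = read_captures(data_paths["captures"])
        feeding = read_feeding(data_paths["feeding"])
        crops = read_crops(data_paths["crops"])
        periods = read_periods(data_paths["periods"])
    except Exception as exc:
        raise StageError("data", str(exc)) from exc
    log("data", f"{len(winter_traces)} winter traces, {len(captures)} captures")

    adult_ids = {t.animal_id for t in winter_traces}
    group_of = {c.animal_id: c.group for c in captures if c.group is not None}

    # --- stage: hibernation ----------------------------------------------
    try:
        summaries = []
        for trace in winter_traces:
            bouts = detect_torpor_bouts(trace, threshold=threshold, min_duration=min_duration_h)
            retained, excluded = exclude_isolated_bouts(bouts, max_gap=max_gap_days)
            summaries.append(summarize_hibernation(trace.animal_id, retained, len(excluded)))
        hib_animals, hib_groups = phenology_table(summaries, group_of)
        write_table(hib_animals, out_dir / "hibernation_summary.csv")
        write_table(hib_groups, out_dir / "hibernation_by_group.csv")
    except Exception as exc:
        raise StageError("hibernation", str(exc)) from exc
    log("hibernation", f"{len(summaries)} animals summarized")

    # --- stage: nutrition -------------------------------------------------
    try:
        intakes = compute_intake(feeding, crops, periods)
        intake_rows = []
        pref_by_group: dict[str, dict[str, list[float]]] = {}
        for s in intakes:
            group = group_of.get(s.animal_id)
            row = {
                "animal_id": s.animal_id,
                "group": group,
                "period": s.period,
                "food_g_d": s.food_intake,
                "energy_kj_d": s.energy_intake,
                "protein_g_d": s.protein_intake,
                "lipid_g_d": s.lipid_intake,
                "carbohydrate_g_d": s.carbohydrate_intake,
            }
            focal = FOCAL_CROP.get(group) if group else None
            if focal and len(DIET_CROPS.get(group, ())) == 2 and s.food_intake > 0:
                frac = preference_fraction(s, focal)
                row["preference_fraction"] = frac
                pref_by_group.setdefault(group, {}).setdefault(s.period, []).append(frac)
            else:
                row["preference_fraction"] = np.nan
            intake_rows.append(row)
        intake_df = pd.DataFrame(intake_rows)
        write_table(intake_df, out_dir / "intake_summary.csv")

        pref_rows = []
        for group, by_period in sorted(pref_by_group.items()):
            for period_name, fracs in sorted(by_period.items()):
                if len(fracs) >= 2:
                    res = preference_test(fracs)
                    pref_rows.append(
                        {
                            "group": group,
                            "period": period_name,
                            "n": len(fracs),
                            "mean_fraction": float(np.mean(fracs)),
                            "statistic": res.statistic,
                            "p_value": res.p_value,
                            "direction": res.direction,
                        }
                    )
        write_table(
            pd.DataFrame(
                pref_rows,
                columns=["group", "period", "n", "mean_fraction", "statistic", "p_value", "direction"],
            ),
            out_dir / "preference_tests.csv",
        )
    except Exception as exc:
        raise StageError("nutrition", str(exc)) from exc
    log("nutrition", f"{len(intakes)} intake summaries")

    # --- stage: reproduction ---------------------------------------------
    try:
        parturitions = {}
        for trace in repro_traces:
            series = daily_means(trace)
            events = detect_parturitions(series, jump=jump, refractory=refractory)
            if events:
                parturitions[trace.animal_id] = events
        pup_captures = [c for c in captures if c.mother_id is not None]
        pup_captures = [c for c in pup_captures if c.mother_id in parturitions]
        certain = flag_certain_first_litter(pup_captures, parturitions)

        first_caps: dict[str, object] = {}
        for c in sorted(pup_captures, key=lambda e: e.date):
            first_caps.setdefault(c.animal_id, c)
        # A pup cannot be trapped before emerging; a "certain" pup whose first
        # capture precedes first parturition + emergence age signals a missed
        # true first parturition, so it is excluded from the anchor fit.
        emergence_min = timedelta(days=config.emergence_age_d)
        certain_birth = {
            p: parturitions[first_caps[p].mother_id][0].date
            for p, flag in certain.items()
            if flag
            and first_caps[p].date
            >= parturitions[first_caps[p].mother_id][0].date + emergence_min
        }
        certain_points = growth_points(
            [c for c in pup_captures if c.animal_id in certain_birth], certain_birth
        )
        models = fit_growth_models(certain_points)
        write_table(
            pd.DataFrame(
                [
                    {
                        "group": m.group,
                        "sex": m.sex,
                        "slope_g_d": m.slope,
                        "intercept_g": m.intercept,
                        "n_pups": m.n_pups,
                        "n_points": m.n_points,
                        "r_squared": m.r_squared,
                    }
                    for m in models.values()
                ]
            ),
            out_dir / "growth_models.csv",
        )

        inferred = {}
        for pup_id, cap in first_caps.items():
            key = (cap.group, cap.sex)
            model = models.get(key)
            if model is None:
                continue
            inferred[pup_id] = (cap.mother_id, infer_birth_date(cap, model))
        assignments = assign_pups(inferred, parturitions, certain_flags=certain)
        write_table(
            pd.DataFrame(
                [
                    {
                        "pup_id": a.pup_id,
                        "mother_id": a.mother_id,
                        "inferred_birth_date": a.inferred_birth_date,
                        "assigned_parturition_date": a.assigned_parturition_date,
                        "litter_number": a.assigned_litter_number,
                        "discrepancy_d": a.discrepancy,
                        "certain_first_litter": a.certain_first_litter,
                    }
                    for a in assignments
                ]
            ),
            out_dir / "pup_assignments.csv",
        )
        pup_sexes = {c.animal_id: c.sex for c in pup_captures}
        litters, litter_metrics = litter_table(assignments, parturitions, pup_sexes)
        write_table(litters, out_dir / "litters.csv")

        window = (config.active_start, config.active_end)
        adult_caps = [c for c in captures if c.animal_id in adult_ids]
        mass_animals, mass_groups = season_mass(adult_caps, window, group_of)
        write_table(mass_animals, out_dir / "season_mass.csv")
        write_table(mass_groups, out_dir / "season_mass_by_group.csv")
    except Exception as exc:
        raise StageError("reproduction", str(exc)) from exc
    log("reproduction", f"{len(parturitions)} mothers, {len(assignments)} pups assigned")

    # --- stage: stats -----------------------------------------------------
    try:
        stats_rows = []

        def add(label: str, res) -> None:
            stats_rows.append(
                {
                    "analysis": label,
                    "test": res.test_name,
                    "statistic_label": res.statistic_label,
                    "statistic": res.statistic_value,
                    "df": str(res.df),
                    "p_value": res.p_value,
                }
            )

        hib = hib_animals.dropna(subset=["group"])
        torpor_by_group = {
            g: sub["total_torpor_h"].to_numpy() for g, sub in hib.groupby("group") if len(sub) >= 2
        }
        if len(torpor_by_group) >= 2:
            add("total torpor time ~ group", compare_groups(torpor_by_group, mode="auto"))

        hibernators = hib[hib["did_hibernate"]]
        if len(hibernators) >= 3:
            add(
                "total torpor vs hibernation duration",
                simple_regression(
                    hibernators["total_torpor_h"], hibernators["hibernation_duration_d"]
                ),
            )

        for period_name in ("hibernation", "post_hibernation"):
            sub = intake_df[intake_df["period"] == period_name].dropna(subset=["group"])
            food = {g: s["food_g_d"].to_numpy() for g, s in sub.groupby("group") if len(s) >= 2}
            if len(food) >= 2:
                add(f"food intake ~ group ({period_name})", compare_groups(food, mode="nonparametric"))
            energy = {g: s["energy_kj_d"].to_numpy() for g, s in sub.groupby("group") if len(s) >= 2}
            if len(energy) >= 2:
                add(f"energy intake ~ group ({period_name})", compare_groups(energy, mode="nonparametric"))

        pups_per_female = litter_metrics["pups_per_female"]
        mothers = [m for m in pups_per_female if m in group_of]
        if len({group_of[m] for m in mothers}) >= 2:
            add(
                "pups per female ~ group (Poisson)",
                count_model(
                    [pups_per_female[m] for m in mothers], [group_of[m] for m in mothers]
                ),
            )

        # body mass at end of winter vs number of litters, diet as random intercept
        n_litters = {m: len(v) for m, v in parturitions.items()}
        mm_rows = [
            {
                "mother": m,
                "litters": n_litters[m],
                "mass": mass_animals.set_index("animal_id")["mean_mass_g"].get(m, np.nan),
                "group": group_of.get(m),
            }
            for m in n_litters
        ]
        mm_df = pd.DataFrame(mm_rows).dropna()
        if len(mm_df) >= 8 and mm_df["group"].nunique() >= 2:
            res = mixed_model(mm_df, "litters", "mass", "group", family="gaussian")
            add("n litters ~ season mass + (1|diet)", res)
            stats_rows[-1]["marginal_r2"] = res.extra["marginal_r2"]

        stats_df = pd.DataFrame(stats_rows)
        write_table(stats_df, out_dir / "stats_report.csv")
    except Exception as exc:
        raise StageError("stats", str(exc)) from exc
    log("stats", f"{len(stats_rows)} analyses")

    # --- report + manifest ------------------------------------------------
    summary_lines = [
        "hiberlitter pipeline report",
        f"animals: {len(winter_traces)} winter traces, {len(repro_traces)} reproduction traces",
        f"torpor: mean total {np.nanmean(hib_animals['total_torpor_h']):.1f} h across "
        f"{int(hib_animals['did_hibernate'].sum())}/{len(hib_animals)} hibernating females",
        f"litters: {sum(len(v) for v in parturitions.values())} parturitions, "
        f"{len(assignments)} pups assigned, "
        f"mean inter-litter interval {litter_metrics['interlitter_interval_mean_d']:.1f} d",
    ]
    (out_dir / "summary.txt").write_text("\n".join(summary_lines) + "\n")

    outputs = sorted(
        p for p in out_dir.rglob("*.csv") if "data" not in p.relative_to(out_dir).parts[:1]
    ) + [out_dir / "summary.txt"]
    manifest = RunManifest(
        config_hash=_config_hash(config),
        seed=config.seed,
        version=__version__,
        checksums={str(p.relative_to(out_dir)): _sha256(p) for p in outputs},
        record_counts={
            "winter_traces": len(winter_traces),
            "captures": len(captures),
            "intake_summaries": len(intakes),
            "parturitions": sum(len(v) for v in parturitions.values()),
            "pup_assignments": len(assignments),
        },
    )
    (out_dir / "manifest.json").write_text(manifest.to_json() + "\n")
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    return manifest
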