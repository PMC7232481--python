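"""Orchestration: simulate-or-load, kinetics, washout, community, report.

A single structured YAML config drives all stages.  Every stage writes its
tables under the output directory and contributes a section to the
:class:`RunReport`, which carries provenance (config hash, seed, package
version) so each reported number is traceable to an artifact file.

Config schema (all keys optional; defaults shown by ``default_config``)::

    seed: 1
    output_dir: out
    stages: [simulate, kinetics, te, substrate, community]
    simulate:            # any SimConfig field; reactors as {id, depleted}
      horizon_days: 350
    kinetics:
      window: 7
      slope_threshold: 15.0
      level_threshold: 1200.0
    community:
      rank: genus
      floor: 0.01
      k_max: 6
      n_perm: 999
      restarts: 20
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import breakpoints, community, substrate, synthetic, washout
from ._version import __version__ as _pkg_version
from .gas import FeedingSchedule, segment_cycles

logger = logging.getLogger(__name__)

__all__ = ["RunReport", "default_config", "run"]

_ALL_STAGES = ("simulate", "kinetics", "te", "substrate", "community")


def default_config() -> dict:
    return {
        "seed": 0,
        "output_dir": None,
        "stages": list(_ALL_STAGES),
        "simulate": {},
        "kinetics": {"window": 7, "slope_threshold": 15.0, "level_threshold": 1200.0},
        "community": {
            "rank": "genus",
            "floor": 0.01,
            "k_max": 6,
            "n_perm": 999,
            "restarts": 20,
        },
    }


@dataclass
class RunReport:
    """Aggregated outputs of one pipeline run."""

    seed: int
    config_hash: str
    version: str
    sections: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config_hash": self.config_hash,
            "version": self.version,
            "sections": self.sections,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, default=_jsonable)

    def to_text(self) -> str:
        lines = [
            "digesterkit run report",
            f"  version     {self.version}",
            f"  seed        {self.seed}",
            f"  config hash {self.config_hash[:16]}",
        ]
        for name, section in self.sections.items():
            lines.append(f"\n[{name}]")
            lines.extend(_format_section(section, indent=2))
        return "\n".join(lines)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _format_section(section, indent: int) -> list[str]:
    pad = " " * indent
    out = []
    if isinstance(section, dict):
        for k, v in section.items():
            if isinstance(v, dict):
                out.append(f"{pad}{k}:")
                out.extend(_format_section(v, indent + 2))
            else:
                out.append(f"{pad}{k}: {v}")
    else:
        out.append(f"{pad}{section}")
    return out


def _build_sim_config(cfg: dict, seed: int) -> synthetic.SimConfig:
    params = dict(cfg.get("simulate") or {})
    reactors = params.pop("reactors", None)
    if reactors is not None:
        params["reactors"] = tuple(
            synthetic.ReactorSpec(r["id"], tuple(r.get("depleted", ())))
            for r in reactors
        )
    for key in ("community_sample_days", "pulse_days"):
        if key in params:
            params[key] = tuple(params[key])
    return synthetic.SimConfig(seed=seed, **params)


def _stage_kinetics(cfg: dict, bundle: synthetic.SimBundle, outdir: Path | None):
    kcfg = {**default_config()["kinetics"], **(cfg.get("kinetics") or {})}
    section = {}
    sim = bundle.config
    for rid, run_ in bundle.runs.items():
        feeds = np.arange(sim.horizon_days) * 1440.0
        schedule = FeedingSchedule(
            feed_times=feeds,
            reactor_volume_l=sim.volume_l,
            hrt_days=sim.hrt_days,
            olr=sim.olr,
        )
        cycles = segment_cycles(run_.gas, schedule)
        trend = breakpoints.breakpoint_series(cycles)
        alarm = breakpoints.detect_drift(
            trend,
            window=int(kcfg["window"]),
            slope_threshold=float(kcfg["slope_threshold"]),
            level_threshold=float(kcfg["level_threshold"]),
        )
        events = run_.events
        section[rid] = {
            "n_cycles": len(cycles),
            "n_trend_entries": len(trend),
            "alarm_day": alarm,
            "propionate_onset_day": events.get("propionate_onset_day"),
            "acetate_onset_day": events.get("acetate_onset_day"),
            "failure_day": events.get("failure_day"),
        }
        if alarm is not None and events.get("propionate_onset_day") is not None:
            section[rid]["lead_days"] = events["propionate_onset_day"] - alarm
        if outdir is not None:
            trend.to_frame(int(kcfg["window"])).to_csv(
                outdir / f"breakpoints_{rid}.tsv", sep="\t", index=False
            )
    return section


def _stage_te(bundle: synthetic.SimBundle, outdir: Path | None):
    sim = bundle.config
    section = {}
    for rid, run_ in bundle.runs.items():
        per_el = {}
        for element, series in run_.te.items():
            milestones = {
                "day_206": round(series.at(min(206.0, sim.horizon_days)), 4),
                "day_229": round(series.at(min(229.0, sim.horizon_days)), 4),
                "day_257": round(series.at(min(257.0, sim.horizon_days)), 4),
            }
            per_el[element] = milestones
            if outdir is not None:
                ng_l = np.array(
                    [washout.nM_to_ng_per_L(c, element) for c in series.concentration]
                )
                pd.DataFrame(
                    {
                        "day": series.time,
                        "nM": series.concentration,
                        "ng_per_L": ng_l,
                        "ng_per_gCOD": ng_l / sim.feed_cod,
                    }
                ).to_csv(outdir / f"te_{rid}_{element}.tsv", sep="\t", index=False)
        section[rid] = per_el
    return section


def _stage_substrate(outdir: Path | None):
    table = substrate.SUBSTRATE_TE_TABLE
    section = {
        "totals_ng_per_L": {
            el: substrate.total_contribution(table, el) for el in ("Co", "Ni", "Se", "W")
        },
        "cod_methane_mL_per_g": substrate.round_sig(substrate.cod_methane_volume(), 3),
    }
    if outdir is not None:
        table.to_csv(outdir / "substrate_te_contributions.tsv")
    return section


def _stage_community(cfg: dict, bundle: synthetic.SimBundle, seed: int, outdir: Path | None):
    ccfg = {**default_config()["community"], **(cfg.get("community") or {})}
    section = {}
    for name, table in (("bacteria", bundle.bacteria), ("archaea", bundle.archaea)):
        counts = table.counts
        div = pd.DataFrame(
            {
                "hill_1D": [community.hill_diversity(row, 1) for row in counts.to_numpy()],
                "hill_1E": [community.hill_evenness(row) for row in counts.to_numpy()],
            },
            index=counts.index,
        )
        hel = community.hellinger(counts.to_numpy())
        dis = community.bray_curtis(counts.to_numpy())
        ord_ = community.nmds(dis, restarts=int(ccfg["restarts"]), seed=seed)
        clus = community.choose_k(hel, k_max=int(ccfg["k_max"]), seed=seed)
        genus = table.aggregate_by_rank(ccfg["rank"])
        iv = community.indval(
            genus, clus.labels, n_perm=int(ccfg["n_perm"]), seed=seed
        )
        top = iv.summary.sort_values("indval", ascending=False).head(5)
        # do the clusters differ in the process state (total VFA) on the day?
        vfa_at_sample = []
        for sid in counts.index:
            rid = table.metadata.loc[sid, "reactor"]
            day = int(table.metadata.loc[sid, "day"])
            daily = bundle.runs[rid].daily
            row = daily[daily["day"] == min(day, int(daily["day"].max()))].iloc[0]
            vfa_at_sample.append(
                float(row["acetate_mM"] + row["propionate_mM"] + row["butyrate_mM"])
            )
        vfa_at_sample = np.asarray(vfa_at_sample)
        groups = [vfa_at_sample[clus.labels == u] for u in np.unique(clus.labels)]
        anova = community.one_way_anova(groups)
        section[name] = {
            "mean_hill_1D": float(div["hill_1D"].mean()),
            "mean_hill_1E": float(div["hill_1E"].mean()),
            "nmds_stress1": ord_.stress,
            "chosen_k": clus.k,
            "weak_structure": clus.weak_structure,
            "top_indicators": {
                str(g): round(float(v), 1) for g, v in top["indval"].items()
            },
            "anova_vfa_F": None if anova.degenerate else round(anova.F, 3),
            "anova_vfa_p": None if anova.degenerate else float(anova.p_value),
        }
        if outdir is not None:
            div.to_csv(outdir / f"diversity_{name}.tsv", sep="\t")
            ord_.to_frame(index=counts.index).assign(stress=ord_.stress).to_csv(
                outdir / f"nmds_{name}.tsv", sep="\t"
            )
            iv.summary.to_csv(outdir / f"indval_{name}.tsv", sep="\t")
            rel = community.aggregate_relative_abundance(
                table, rank=ccfg["rank"], floor=float(ccfg["floor"])
            )
            rel.to_csv(outdir / f"composition_{name}.tsv", sep="\t")
    return section


def run(config: dict | str | Path | None = None) -> RunReport:
    """Execute the configured stages in dependency order.

    ``config`` is a YAML path or an already-parsed mapping; omitted keys
    fall back to defaults.  The run is idempotent for a fixed seed.  Any
    stage failure propagates with the stage name attached.
    """
    if config is None:
        cfg = default_config()
    elif isinstance(config, (str, Path)):
        with open(config) as fh:
            cfg = {**default_config(), **(yaml.safe_load(fh) or {})}
    else:
        cfg = {**default_config(), **config}
    seed = int(cfg.get("seed", 0))
    stages = list(cfg.get("stages") or _ALL_STAGES)
    unknown = set(stages) - set(_ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    outdir = Path(cfg["output_dir"]) if cfg.get("output_dir") else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    canonical = yaml.safe_dump(cfg, sort_keys=True, default_flow_style=True)
    report = RunReport(
        seed=seed,
        config_hash=hashlib.sha256(canonical.encode()).hexdigest(),
        version=_pkg_version,
    )

    bundle = None
    needs_sim = {"simulate", "kinetics", "te", "community"} & set(stages)
    if needs_sim:
        try:
            sim_cfg = _build_sim_config(cfg, seed)
            bundle = synthetic.simulate(sim_cfg)
        except Exception as exc:
            raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc
        if "simulate" in stages:
            report.sections["simulate"] = {
                "reactors": [r.id for r in sim_cfg.reactors],
                "horizon_days": sim_cfg.horizon_days,
                "events": {rid: r.events for rid, r in bundle.runs.items()},
            }
            if outdir is not None:
                for rid, run_ in bundle.runs.items():
                    run_.daily.to_csv(outdir / f"daily_{rid}.tsv", sep="\t", index=False)
                    run_.vfa.to_csv(outdir / f"vfa_{rid}.tsv", sep="\t", index=False)
                    gas_df = run_.gas.to_frame()
                    gas_df.to_csv(
                        outdir / f"gas_{rid}.csv", index=False, float_format="%.6g"
                    )
                bundle.bacteria.to_tsv(
                    outdir / "asv_bacteria.tsv", outdir / "samples.tsv"
                )
                bundle.archaea.to_tsv(outdir / "asv_archaea.tsv")

    for stage in stages:
        if stage == "simulate":
            continue
        try:
            if stage == "kinetics":
                report.sections["kinetics"] = _stage_kinetics(cfg, bundle, outdir)
            elif stage == "te":
                report.sections["te"] = _stage_te(bundle, outdir)
            elif stage == "substrate":
                report.sections["substrate"] = _stage_substrate(outdir)
            elif stage == "community":
                report.sections["community"] = _stage_community(cfg, bundle, seed, outdir)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    if outdir is not None:
        (outdir / "report.json").write_text(report.to_json())
        (outdir / "report.txt").write_text(report.to_text())
    return report
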