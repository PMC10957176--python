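"""End-to-end report assembly.

``build_report`` runs whichever pipeline stages a config dictionary
requests — RTA decay fitting, CFSE doubling time, cellular censuses,
monosome/polysome partition, and the capacity accounting — and
assembles one JSON-serializable report with every intermediate
quantity, the constants used, and any warnings. The report is
deterministic given the inputs and seeds.

Config blocks (all optional except that at least one must be present):

constants:      overrides for :class:`~riboaccount.constants.PhysicalConstants`
rta:            {events_csv | points, fix_plateau?, bootstrap?, seed?}
proliferation:  {observations: [{time_hr, mfi}, ...]} (first row is the reference)
census:         {diameter_um?, protein: {...}?, ribosomes: {...}?}
partition:      {m?, f?, profile_csv?+regions?, blot?}
accounting:     {p_over_r | proteins_per_cell+functional_ribosomes,
                 elongation_rate_aa_per_s, measured_doubling_hr?,
                 drip_fraction?, protein_half_life_hr?, active_ribosome_fraction?}
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import pandas as pd

from . import accounting as acc
from . import census as cen
from . import partition as par
from . import proliferation as pro
from . import rta
from .constants import PhysicalConstants

KNOWN_BLOCKS = ("constants", "rta", "proliferation", "census", "partition", "accounting")


def _round_report(x: float | None, ndigits: int = 4) -> float | None:
    return None if x is None else round(x, ndigits)


def build_report(config: dict[str, Any]) -> dict[str, Any]:
    """Run the stages named in ``config`` and assemble one structured report."""
    stages = [k for k in config if k in KNOWN_BLOCKS and k != "constants"]
    if not stages:
        raise ValueError(
            f"config requests no pipeline stage; provide at least one of "
            f"{[b for b in KNOWN_BLOCKS if b != 'constants']}"
        )
    constants = PhysicalConstants(**config.get("constants", {}))
    report: dict[str, Any] = {
        "schema_version": acc.REPORT_SCHEMA_VERSION,
        "constants": json.loads(constants.model_dump_json()),
        "warnings": [],
    }

    if "rta" in config:
        report["rta"] = _run_rta(config["rta"])
    if "proliferation" in config:
        report["proliferation"] = _run_proliferation(config["proliferation"])
    if "census" in config:
        report["census"] = _run_census(config["census"], constants)
    if "partition" in config:
        report["partition"] = _run_partition(config["partition"])
    if "accounting" in config:
        report["accounting"] = _run_accounting(
            config["accounting"], report, constants
        )
    return report


def _run_rta(block: dict[str, Any]) -> dict[str, Any]:
    if "events_csv" in block:
        events = pd.read_csv(block["events_csv"])
        if block.get("bootstrap"):
            fit, _ = rta.bootstrap_t_half_from_events(
                events,
                n_boot=int(block["bootstrap"]),
                seed=int(block.get("seed", 0)),
                fix_plateau=block.get("fix_plateau"),
            )
        else:
            points = rta.summarize_rpm(events)
            fit = rta.fit_one_phase_decay(points, fix_plateau=block.get("fix_plateau"))
        points = rta.summarize_rpm(events)
    elif "points" in block:
        points = pd.DataFrame(block["points"])
        fit = rta.fit_one_phase_decay(points, fix_plateau=block.get("fix_plateau"))
    else:
        raise ValueError("rta block requires 'events_csv' or 'points'")
    est = rta.elongation_rate_from_half_life(fit.t_half_s)
    return {
        "s0": _round_report(fit.s0),
        "span": _round_report(fit.span),
        "plateau": _round_report(fit.plateau),
        "lambda_per_s": _round_report(fit.lambda_per_s, 6),
        "t_half_s": _round_report(fit.t_half_s, 2),
        "ci_t_half_s": list(fit.ci_t_half) if fit.ci_t_half else None,
        "stalled_fraction": _round_report(rta.stalled_fraction(fit)),
        "elongation_rate_aa_per_s": _round_report(est.rate_aa_per_s, 1),
        "elongation_percent_change": _round_report(est.percent_change, 0),
        "n_points": fit.n_points,
    }


def _run_proliferation(block: dict[str, Any]) -> dict[str, Any]:
    obs = block["observations"]
    if len(obs) < 3:
        raise ValueError(
            "proliferation block needs >= 3 observations: an undivided "
            "reference plus two timepoints"
        )
    ref = obs[0]
    g = [pro.mean_divisions_from_mfi(o["mfi"], ref["mfi"]) for o in obs[1:]]
    t = [o["time_hr"] for o in obs[1:]]
    est = pro.doubling_time(g[0], t[0], g[-1], t[-1])
    return {
        "generations": [_round_report(x, 3) for x in g],
        "doubling_time_hr": _round_report(est.doubling_time_hr, 2),
        "interval_hr": [est.interval_start_hr, est.interval_end_hr],
    }


def _run_census(block: dict[str, Any], constants: PhysicalConstants) -> dict[str, Any]:
    out: dict[str, Any] = {}
    volume_fl = None
    if "diameter_um" in block:
        geom = cen.volume_from_diameter(block["diameter_um"])
        volume_fl = geom.volume_fl
        out["volume"] = {
            "diameter_um": geom.diameter_um,
            "volume_fl": _round_report(geom.volume_fl, 1),
        }
    if "protein" in block:
        p = block["protein"]
        census = cen.protein_census_from_plate(
            pd.read_csv(p["plate_csv"]),
            sampled_fraction=p["sampled_fraction"],
            n_cells=p["n_cells"],
            volume_fl=volume_fl,
            constants=constants,
        )
        out["protein"] = {
            "mass_pg_per_cell": _round_report(census.mass_pg_per_cell, 2),
            "proteins_per_cell": census.proteins_per_cell,
            "proteins_per_fl": census.proteins_per_fl,
        }
    if "ribosomes" in block:
        r = block["ribosomes"]
        windows = {k: tuple(v) for k, v in r.get("windows", cen.DEFAULT_RRNA_WINDOWS).items()}
        census = cen.ribosome_census_from_traces(
            pd.read_csv(r["sample_trace_csv"]),
            pd.read_csv(r["standard_trace_csv"]),
            windows=windows,
            eluate_volume_ul=r["eluate_volume_ul"],
            n_cells=r["n_cells"],
            organism=r.get("organism", "mouse"),
            constants=constants,
        )
        out["ribosomes"] = {
            "copies_18s_per_cell": census.copies_18s_per_cell,
            "copies_28s_per_cell": census.copies_28s_per_cell,
            "functional_ribosomes_per_cell": census.functional_ribosomes_per_cell,
            "rna_yield": _round_report(census.rna_yield),
        }
    if not out:
        raise ValueError("census block requests no measurement")
    return out


def _run_partition(block: dict[str, Any]) -> dict[str, Any]:
    if "m" in block:
        m = float(block["m"])
    elif "profile_csv" in block:
        regions = {k: tuple(v) for k, v in block["regions"].items()}
        m = par.monosome_ribosome_fraction(pd.read_csv(block["profile_csv"]), regions)
    else:
        raise ValueError("partition block requires 'm' or 'profile_csv'")
    if "f" in block:
        f = float(block["f"])
    elif "blot" in block:
        f = par.translating_monosome_fraction(par.DotBlotQuant(**block["blot"]))
    else:
        raise ValueError("partition block requires 'f' or 'blot'")
    return {
        "monosome_ribosome_fraction": _round_report(m),
        "translating_monosome_fraction": _round_report(f),
        "monosome_translation_share": _round_report(par.monosome_translation_share(f, m)),
    }


def _run_accounting(
    block: dict[str, Any], report: dict[str, Any], constants: PhysicalConstants
) -> dict[str, Any]:
    if "p_over_r" in block:
        proteins, ribosomes = float(block["p_over_r"]), 1.0
    else:
        proteins = float(block["proteins_per_cell"])
        ribosomes = float(block["functional_ribosomes"])
    rate = block.get("elongation_rate_aa_per_s")
    if rate is None and "rta" in report:
        rate = report["rta"]["elongation_rate_aa_per_s"]
    if rate is None:
        raise ValueError("accounting block requires 'elongation_rate_aa_per_s' (or an rta stage)")
    doubling = block.get("measured_doubling_hr")
    if doubling is None and "proliferation" in report:
        doubling = report["proliferation"]["doubling_time_hr"]
    inp = acc.AccountingInput(
        proteins_per_cell=proteins,
        functional_ribosomes=ribosomes,
        elongation_rate_aa_per_s=float(rate),
        avg_protein_length_aa=constants.avg_protein_length_aa,
        measured_doubling_hr=doubling,
        drip_fraction=float(block.get("drip_fraction", 0.30)),
        protein_half_life_hr=block.get("protein_half_life_hr", 32.0),
        active_ribosome_fraction=float(block.get("active_ribosome_fraction", 1.0)),
    )
    res = acc.run_accounting(inp)
    return {
        "protein_per_ribosome": _round_report(res.protein_per_ribosome, 1),
        "min_duplication_hr": _round_report(res.min_duplication_hr, 1),
        "corrected_duplication_hr": _round_report(res.corrected_duplication_hr, 1),
        "feasible": res.feasible,
        "paradox_ratio": _round_report(res.paradox_ratio, 1),
        "required_rate_aa_per_s": _round_report(res.required_rate_aa_per_s, 1),
        "measured_doubling_hr": doubling,
    }


def write_report(report: dict[str, Any], path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
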