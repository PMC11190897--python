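"""Config-driven orchestration of the analysis stages.

A YAML run config toggles stages and overrides stage parameters; every
stochastic stage derives its seed from the global seed by stable hashing
of the stage name, so one seed fixes the whole run. Outputs are per-stage
TSVs plus a machine-readable ``summary.json`` and a short plain-text
report. Re-running with identical config and inputs rewrites identical
outputs.
"""

from __future__ import annotations

import json
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bulk_de, calcium, cellcount, enrichment, nerve, receptor_map, simulate

STAGES = ("de", "enrichment", "receptors", "calcium", "nerve", "cells")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": list(STAGES),
    "out_dir": "nocimap_run",
    "de": {
        "n_genes": 1200,
        "n_samples_per_group": 8,
        "n_de_genes": 80,
        "dispersion": 0.2,
        "min_cpm": 1.0,
        "min_samples_per_group": 2,
        "alpha": 1e-4,
        "use_fdr": True,
    },
    "enrichment": {"n_terms": 8, "term_size": 30, "n_permutations": 300},
    "receptors": {"n_cells": 314, "tpm_threshold": 0.0, "min_coverage": 0.10},
    "calcium": {
        "n_rois": 300,
        "responder_fraction": 0.4,
        "noise_sd": 0.02,
        "dead_fraction": 0.05,
    },
    "nerve": {
        "duration_s": 120.0,
        "drug_window": [60.0, 120.0],
        "amplitude_uv": 90.0,
        "noise_uv": 15.0,
        "baseline_rate_hz": 2.0,
        "drug_rate_hz": 12.0,
    },
    "cells": {"n_green": 10, "n_blue_only": 40},
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    return merge_config(cfg)


def merge_config(cfg: dict) -> dict:
    unknown = set(cfg) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    merged = {k: (v.copy() if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for k, v in cfg.items():
        if isinstance(v, dict):
            bad = set(v) - set(DEFAULT_CONFIG[k])
            if bad:
                raise ValueError(f"unknown keys in config block {k!r}: {sorted(bad)}")
            merged[k].update(v)
        else:
            merged[k] = v
    return merged


def run_pipeline(config: dict, out_dir=None) -> dict:
    """Execute the enabled stages on synthetic inputs; return the summary."""
    cfg = merge_config(config)
    out = Path(out_dir if out_dir is not None else cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    (out / "resolved_config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    seed = int(cfg["seed"])
    summary: dict = {"seed": seed, "stages": {}}

    de_table = None
    if "de" in cfg["stages"]:
        p = cfg["de"]
        sim_cfg = simulate.SimulationConfig(
            seed=stage_seed(seed, "de"),
            n_genes=p["n_genes"],
            n_samples_per_group=p["n_samples_per_group"],
            n_de_genes=p["n_de_genes"],
            dispersion=p["dispersion"],
        )
        cm, truth = simulate.simulate_bulk_counts(sim_cfg)
        cm = bulk_de.filter_low_counts(cm, p["min_cpm"], p["min_samples_per_group"])
        factors = bulk_de.tmm_factors(cm)
        disp = bulk_de.estimate_dispersion(cm, factors)
        de_table = bulk_de.nb_exact_test(cm, factors, disp, "case", "control")
        de_table.to_csv(out / "de.tsv", sep="\t", index=False)
        sig = de_table[
            (de_table["fdr" if p["use_fdr"] else "pvalue"] <= p["alpha"])
        ]
        truth_set = set(truth["de_gene_ids"]) & set(de_table["gene_id"])
        hits = set(sig["gene_id"])
        big = {
            g for g in truth_set if abs(truth["log2fc"][g]) >= 1.0
        }
        summary["stages"]["de"] = {
            "n_genes_tested": int(len(de_table)),
            "n_significant": int(len(sig)),
            "common_dispersion": disp.common,
            "sensitivity_lfc_ge_1": (len(hits & big) / len(big)) if big else float("nan"),
        }

    if "enrichment" in cfg["stages"]:
        p = cfg["enrichment"]
        rng = np.random.default_rng(stage_seed(seed, "enrichment"))
        universe = [f"gene{i:05d}" for i in range(1000)]
        terms = {
            f"term_{t}": set(rng.choice(universe, size=p["term_size"], replace=False))
            for t in range(p["n_terms"])
        }
        lib = enrichment.GeneSetLibrary(terms, set(universe))
        # query enriched for term_0
        q = set(rng.choice(sorted(lib.terms["term_0"]), size=p["term_size"] // 2, replace=False))
        q |= set(rng.choice(universe, size=20, replace=False))
        table = enrichment.enrich(
            q, lib, n_permutations=p["n_permutations"], seed=stage_seed(seed, "enrichment")
        )
        table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        summary["stages"]["enrichment"] = {
            "top_term": str(table.iloc[0]["term"]),
            "top_combined_score": float(table.iloc[0]["combined_score"]),
        }

    if "receptors" in cfg["stages"] and de_table is not None:
        p = cfg["receptors"]
        tpm, pops, truth = _synthetic_neurons(p["n_cells"], stage_seed(seed, "receptors"))
        mr = receptor_map.MediatorReceptorMap(
            {"gene00000": ["Agtr1a", "Agtr1b"], "gene00001": ["Il1r1"]}
        )
        present = {m: r for m, r in mr.pairs.items() if m in de_table.index}
        if present:
            table = receptor_map.prioritize_mediators(
                de_table,
                receptor_map.MediatorReceptorMap(present),
                tpm,
                tpm_threshold=p["tpm_threshold"],
                min_coverage=p["min_coverage"],
            )
            table.to_csv(out / "prioritization.tsv", sep="\t", index=False)
            summary["stages"]["receptors"] = {
                "n_mediators": int(len(table)),
                "n_selected": int(table["selected"].sum()),
            }

    if "calcium" in cfg["stages"]:
        p = cfg["calcium"]
        ts, truth = simulate.simulate_trace_set(
            n_rois=p["n_rois"],
            responder_fraction=p["responder_fraction"],
            noise_sd=p["noise_sd"],
            dead_fraction=p["dead_fraction"],
            seed=stage_seed(seed, "calcium"),
        )
        calls = calcium.analyse_trace_set(ts)
        calls.to_csv(out / "calcium_calls.tsv", sep="\t", index=False)
        inc = calls[calls["qc_included"]]
        summary["stages"]["calcium"] = {
            "n_rois": int(len(calls)),
            "n_included": int(len(inc)),
            "responder_fraction": float(inc["responsive_drug"].mean()),
        }

    if "nerve" in cfg["stages"]:
        p = cfg["nerve"]
        rec, truth = simulate.simulate_recording(
            duration_s=p["duration_s"],
            drug_window=tuple(p["drug_window"]),
            units=[
                simulate.UnitSpec(p["amplitude_uv"], p["baseline_rate_hz"], p["drug_rate_hz"])
            ],
            noise_uv=p["noise_uv"],
            seed=stage_seed(seed, "nerve"),
        )
        train = nerve.detect_spikes(rec, noise_window=(0.0, min(30.0, p["drug_window"][0])))
        hist, pc = nerve.rate_and_peak_change(
            train,
            drug_onset_s=p["drug_window"][0],
            smooth_s=10.0,
            baseline_span_s=min(300.0, p["drug_window"][0]),
        )
        hist.to_csv(out / "rate_hist.tsv", sep="\t", header=True)
        summary["stages"]["nerve"] = {
            "n_spikes": int(len(train.times_s)),
            "baseline_rate_hz": pc.baseline_rate,
            "peak_rate_hz": pc.peak_rate,
            "delta_hz": pc.delta,
        }

    if "cells" in cfg["stages"]:
        p = cfg["cells"]
        img, truth = simulate.simulate_micrograph(
            p["n_green"], p["n_blue_only"], seed=stage_seed(seed, "cells")
        )
        green = cellcount.count_channel(img[0])
        blue = cellcount.count_channel(img[1])
        res = cellcount.neuron_fraction(green, blue)
        summary["stages"]["cells"] = {
            "n_neurons": res["n_neurons"],
            "n_nuclei": res["n_nuclei"],
            "ratio": res["ratio"],
            "truth_ratio": truth["neuron_fraction"],
        }

    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    _write_report(summary, out / "report.txt")
    return summary


def _synthetic_neurons(n_cells: int, seed: int):
    specs = [
        simulate.GeneSpec("Agtr1a", default_rate=0.55),
        simulate.GeneSpec("Agtr1b", default_rate=0.25),
        simulate.GeneSpec("Il1r1", default_rate=0.8),
        simulate.GeneSpec("Scn10a", conditional_on=("Agtr1a", 0.95, 0.6)),
        simulate.GeneSpec("Trpv1", conditional_on=("Agtr1a", 0.8, 0.5)),
    ]
    return simulate.simulate_neuron_expression(
        n_cells, {"colonic": 1.0}, specs, seed=seed
    )


def _write_report(summary: dict, path: Path) -> None:
    lines = [f"nocimap run (seed {summary['seed']})", ""]
    for stage, vals in summary["stages"].items():
        lines.append(f"[{stage}]")
        for k, v in vals.items():
            lines.append(f"  {k}: {v}")
        lines.append("")
    Path(path).write_text("\n".join(lines))
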