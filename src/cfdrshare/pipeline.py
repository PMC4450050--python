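"""Full-pipeline orchestration with a reproducible run manifest.

A run config (YAML) names at least two phenotypes, each with a summary-
statistic file and study sizes, plus a shared-control count per pair:

    phenotypes:
      T1D: {stats: t1d.tsv, n_cases: 12175, n_controls: 15171}
      RA:  {stats: ra.tsv,  n_cases: 11475, n_controls: 15870}
    shared_controls:
      - {pair: [T1D, RA], n: 8430}
    null_panel: null_ids.txt      # optional, enables genomic control
    qc: qc.tsv                    # optional QC summary table
    gw_threshold: 5.0e-8
    alpha_grid_size: 200

Every ordered pair (principal, conditional) is processed independently
(the conditional FDR is not symmetric in its arguments).  Stages:
QC filter -> genomic control -> harmonise -> mixture fit -> expected-
quantile adjustment -> cFDR table + thresholds -> declared set -> region
FDR bound.  All artifacts are TSV/JSON under the output directory and a
manifest records config, input digests, seeds and per-stage counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cfdr import calibrate_thresholds, cfdr_table, declare
from .genomic_control import apply_gc, estimate_lambda
from .io_design import (
    ConfigurationError,
    StudyPairDesign,
    harmonize,
    qc_filter,
    read_summary,
    write_table,
)
from .null_mixture import fit_em
from .region import build_region, largest_rectangle
from .shared_control import BivariateNullSpec

logger = logging.getLogger(__name__)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def validate_config(config: dict) -> dict:
    """Check the run config before any computation starts."""
    phenos = config.get("phenotypes") or {}
    if len(phenos) < 2:
        raise ConfigurationError("config must name at least 2 phenotypes")
    for name, entry in phenos.items():
        for key in ("stats", "n_cases", "n_controls"):
            if key not in entry:
                raise ConfigurationError(f"phenotype {name!r} lacks {key!r}")
    shared = {}
    for item in config.get("shared_controls", []):
        a, b = item["pair"]
        for p in (a, b):
            if p not in phenos:
                raise ConfigurationError(f"unknown phenotype {p!r} in pair")
        shared[frozenset((a, b))] = int(item["n"])
    names = sorted(phenos)
    for a in names:
        for b in names:
            if a < b and frozenset((a, b)) not in shared:
                raise ConfigurationError(
                    f"missing shared-control count for pair ({a}, {b})"
                )
    config["_shared_lookup"] = shared
    return config


def design_for(config: dict, principal: str, conditional: str) -> StudyPairDesign:
    phenos = config["phenotypes"]
    n0 = config["_shared_lookup"][frozenset((principal, conditional))]
    pi, pj = phenos[principal], phenos[conditional]
    return StudyPairDesign(
        n_cases_i=int(pi["n_cases"]),
        n_cases_j=int(pj["n_cases"]),
        n_controls_unique_i=int(pi["n_controls"]) - n0,
        n_controls_unique_j=int(pj["n_controls"]) - n0,
        n_controls_shared=n0,
    )


def run_pipeline(config: dict, out_dir, seed: int = 0,
                 base_dir=None) -> dict:
    """Run the full analysis for every ordered phenotype pair.

    Returns the manifest dict (also written to ``out_dir/manifest.json``).
    """
    config = validate_config(dict(config))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base = Path(base_dir) if base_dir else Path(".")

    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "config": {k: v for k, v in config.items() if not k.startswith("_")},
        "inputs": {},
        "stages": {},
        "pairs": {},
    }

    qc_df = None
    if config.get("qc"):
        qc_path = base / config["qc"]
        qc_df = pd.read_csv(qc_path, sep="\t")
        manifest["inputs"][str(qc_path)] = _sha256(qc_path)

    null_ids = None
    if config.get("null_panel"):
        panel_path = base / config["null_panel"]
        null_ids = set(panel_path.read_text().split())
        manifest["inputs"][str(panel_path)] = _sha256(panel_path)

    # stage 1: read, QC, genomic control per phenotype
    studies: dict[str, pd.DataFrame] = {}
    for name, entry in config["phenotypes"].items():
        path = base / entry["stats"]
        manifest["inputs"][str(path)] = _sha256(path)
        df = read_summary(path, entry.get("columns"))
        n_read = len(df)
        res = qc_filter(df, qc=qc_df)
        df = res.records
        lam = None
        if null_ids:
            panel = df.loc[df["snp_id"].isin(null_ids), "z"]
            gc = estimate_lambda(panel.to_numpy())
            lam = gc.lambda_gc
            df = apply_gc(df, lam)
        studies[name] = df
        write_table(df, out / f"{name}.stats.tsv")
        manifest["stages"][name] = {
            "n_read": n_read, "n_after_qc": len(res.records),
            "qc_removed": res.removed, "lambda_gc": lam,
        }

    gw = float(config.get("gw_threshold", 5e-8))
    grid_size = int(config.get("alpha_grid_size", 200))

    for principal in config["phenotypes"]:
        for conditional in config["phenotypes"]:
            if principal == conditional:
                continue
            tag = f"{principal}_given_{conditional}"
            design = design_for(config, principal, conditional)
            pairs = harmonize(studies[principal], studies[conditional])
            if pairs.empty:
                manifest["pairs"][tag] = {"n_snps": 0, "skipped": True}
                continue
            mixture = fit_em(pairs["z_j"].to_numpy())
            spec = BivariateNullSpec.from_design(design, mixture)
            table = cfdr_table(pairs, spec)
            write_table(table, out / f"{tag}.cfdr.tsv")
            thresholds = calibrate_thresholds(table, p_gw=gw)
            declared = declare(table, thresholds)
            pd.Series(declared, name="snp_id").to_csv(
                out / f"{tag}.declared.tsv", sep="\t", index=False
            )
            info = {
                "n_snps": len(pairs),
                "rho": spec.rho,
                "pi0": mixture.pi0,
                "sigma2": mixture.sigma2,
                "beta_i": thresholds.beta_i,
                "alpha_ji": thresholds.alpha_ji,
                "capped": thresholds.capped,
                "thresholds_defined": thresholds.defined,
                "n_declared": int(len(declared)),
            }
            if thresholds.defined and len(declared):
                region = build_region(pairs, thresholds.alpha_ji, spec,
                                      grid_size=grid_size)
                if not region.empty:
                    region = largest_rectangle(region, pairs, spec, len(pairs))
                    info.update(v_l=region.v_l, v_m=region.v_m,
                                alpha_star=region.alpha_star,
                                fdr_bound=region.bound)
                    region_doc = {
                        "alpha": region.alpha,
                        "v_l": region.v_l, "v_m": region.v_m,
                        "m_star": region.m_star,
                        "alpha_star": region.alpha_star,
                        "bound": region.bound,
                        "boundary": region.boundary.to_dict("list"),
                    }
                    (out / f"{tag}.region.json").write_text(
                        json.dumps(region_doc, indent=1)
                    )
            manifest["pairs"][tag] = info

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, default=_json_default)
    )
    return manifest


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
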