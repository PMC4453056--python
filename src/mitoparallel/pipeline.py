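"""Config-driven orchestration of the four analysis stages.

A run config is a YAML mapping with an ``out_dir``, a ``seed`` and one
optional block per stage (``simulate``, ``census``, ``conservation``,
``composition``, ``deficiency``). Every parameter that affects a number in
any output lands in the run's provenance JSON.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Optional, Union

import yaml

from . import __version__
from .alignments import parse_structure_alignment
from .census import build_census, write_census_tsv
from .composition import (
    HBondWeights,
    composition,
    composition_to_frame,
    default_helix_set,
    load_helix_set,
    read_basepair_tsv,
)
from .conservation import conservation_profiles, profiles_to_frame
from .deficiency import compare_with_accessory
from .genbank import parse_genbank_record
from .structures import parse_structure
from . import simulate as sim

_STAGES = ("simulate", "census", "conservation", "composition", "deficiency")


class ConfigError(ValueError):
    pass


def load_config(path: Union[str, Path]) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    validate_config(cfg)
    return cfg


def validate_config(cfg: Any) -> None:
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    if "out_dir" not in cfg:
        raise ConfigError("config field 'out_dir' is required")
    seed = cfg.get("seed", 0)
    if not isinstance(seed, int):
        raise ConfigError(f"config field 'seed' must be an integer, got {seed!r}")
    unknown = set(cfg) - set(_STAGES) - {"out_dir", "seed", "log_level"}
    if unknown:
        raise ConfigError(f"unknown config fields: {sorted(unknown)}")
    defic = cfg.get("deficiency") or {}
    for field, kind in (("radius", (int, float)), ("rho_threshold", int)):
        if field in defic and not isinstance(defic[field], kind):
            raise ConfigError(
                f"config field 'deficiency.{field}' must be numeric, "
                f"got {defic[field]!r}"
            )
    for stage in _STAGES:
        block = cfg.get(stage)
        if block is not None and not isinstance(block, dict):
            raise ConfigError(f"config field '{stage}' must be a mapping")


def run_pipeline(cfg: Union[dict, str, Path]) -> dict:
    """Execute the configured stages; returns a provenance record."""
    if not isinstance(cfg, dict):
        cfg = load_config(cfg)
    else:
        validate_config(cfg)
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    outputs: dict[str, str] = {}

    # declared inputs must exist before any stage runs
    for stage in ("census", "conservation", "composition", "deficiency"):
        block = cfg.get(stage) or {}
        for key in ("genomes_dir", "alignment", "sites", "groups", "pairs",
                    "pairs_b", "helices", "structure"):
            val = block.get(key)
            if val is not None and not Path(val).exists():
                raise ConfigError(f"{stage}.{key}: missing input file {val}")

    if "simulate" in cfg and cfg["simulate"] is not None:
        sim_cfg = cfg["simulate"]
        sim_dir = out_dir / "simulated"
        if "genomes" in sim_cfg:
            g = sim_cfg["genomes"]
            sim.gen_genomes(g.get("n", 10), g.get("scenario", "census_demo"),
                            seed, sim_dir / "genomes")
            cfg.setdefault("census", {}).setdefault(
                "genomes_dir", str(sim_dir / "genomes"))
        if "alignment" in sim_cfg:
            a = sim_cfg["alignment"]
            sim.gen_alignment(
                a.get("n_seqs", 300), a.get("n_sites", 50),
                a.get("p_canonical", 0.9), a.get("p_gap", 0.1),
                seed, sim_dir / "alignment",
            )
            cons = cfg.setdefault("conservation", {})
            cons.setdefault("alignment", str(sim_dir / "alignment/aln.fasta"))
            cons.setdefault("sites", str(sim_dir / "alignment/sites.tsv"))
            cons.setdefault("groups", str(sim_dir / "alignment/groups.tsv"))
        if "pairs" in sim_cfg:
            p = sim_cfg["pairs"]
            sim.gen_basepair_list(
                p.get("n_pairs", 722), p.get("frac_gc", 0.57),
                p.get("frac_au", 0.38), p.get("frac_gu", 0.05),
                p.get("helix_labels", ["H1"]), seed, sim_dir / "pairs.tsv",
            )
            cfg.setdefault("composition", {}).setdefault(
                "pairs", str(sim_dir / "pairs.tsv"))
        if "structure" in sim_cfg:
            s = sim_cfg["structure"]
            sim.gen_structure(
                s.get("scenario", "core_plus_accessory"), seed,
                sim_dir / "structure.pdb",
                n_res=s.get("n_res", 40),
                rho_threshold=s.get("rho_threshold", 5),
            )
            d = cfg.setdefault("deficiency", {})
            d.setdefault("structure", str(sim_dir / "structure.pdb"))
            d.setdefault("core", ["A"])
            d.setdefault("accessory", ["B"])
            d.setdefault("rho_threshold", s.get("rho_threshold", 5))
        outputs["simulate"] = str(sim_dir)

    if "census" in cfg and cfg["census"] is not None:
        c = cfg["census"]
        genomes = [
            parse_genbank_record(p.read_text())
            for p in sorted(Path(c["genomes_dir"]).glob("*.gbk"))
        ]
        rows = build_census(genomes, exclude_groups=c.get("exclude_groups", ()))
        path = out_dir / "census.tsv"
        write_census_tsv(rows, path)
        outputs["census"] = str(path)

    if "conservation" in cfg and cfg["conservation"] is not None:
        c = cfg["conservation"]
        aln = parse_structure_alignment(
            Path(c["alignment"]), Path(c["sites"]),
            Path(c["groups"]) if c.get("groups") else None,
        )
        profiles = conservation_profiles(
            aln, descending=c.get("descending", True)
        )
        path = out_dir / "conservation_profiles.tsv"
        profiles_to_frame(profiles).to_csv(path, sep="\t", index=False)
        outputs["conservation"] = str(path)

    if "composition" in cfg and cfg["composition"] is not None:
        c = cfg["composition"]
        pairs = read_basepair_tsv(c["pairs"])
        helix_set = (
            load_helix_set(c["helices"]) if c.get("helices") else default_helix_set()
        )
        weights = HBondWeights(**c.get("weights", {}))
        report = composition(pairs, helix_set, weights,
                             canonical_only=c.get("canonical_only", False))
        path = out_dir / "composition.tsv"
        composition_to_frame(report).to_csv(path, sep="\t", index=False)
        outputs["composition"] = str(path)

    if "deficiency" in cfg and cfg["deficiency"] is not None:
        c = cfg["deficiency"]
        st = parse_structure(c["structure"])
        without, with_acc = compare_with_accessory(
            st, c.get("core", ["A"]), c.get("accessory", []),
            radius=c.get("radius", 6.5),
            rho_threshold=c.get("rho_threshold", 19),
        )
        path = out_dir / "deficiency.json"
        path.write_text(json.dumps(
            {
                "minus_accessory": _report_dict(without),
                "plus_accessory": _report_dict(with_acc),
            },
            indent=1,
        ))
        outputs["deficiency"] = str(path)

    provenance = {
        "package_version": __version__,
        "seed": seed,
        "config": _jsonable(cfg),
        "config_hash": hashlib.sha256(
            json.dumps(_jsonable(cfg), sort_keys=True).encode()
        ).hexdigest(),
        "outputs": outputs,
    }
    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=1))
    return provenance


def _report_dict(report) -> dict:
    return {
        "subset_label": report.subset_label,
        "n_hbonds": report.n_hbonds,
        "n_underprotected": report.n_underprotected,
        "deficiency_pct": report.deficiency_pct,
        "parameters": report.parameters,
        "per_bond": [
            {"donor": list(w.hbond.donor), "acceptor": list(w.hbond.acceptor),
             "rho": w.rho, "underprotected": w.underprotected}
            for w in report.per_bond
        ],
    }


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj
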