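"""One-config orchestration of the full transporter analysis.

A YAML run configuration names the inputs (structures, spectra, MST tables,
sequences) and per-module parameter overrides; :func:`run_pipeline` executes
the requested blocks in dependency order and collects one JSON-serialisable
report block per module. Failures are recorded per block without aborting
independent blocks, so a partially valid configuration still yields every
result it can support. Re-running an identical configuration reproduces a
byte-identical report body (the timestamp lives outside the body).
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .contacts_interfaces import find_disulfides, interface_report, polar_contacts
from .corrin_geometry import axial_geometry
from .ligand_transplant import transplant
from .sequence_conservation import global_align, map_conservation, percent_identity, read_fasta
from .spectra_binding import Spectrum, compare_spectra, fit_kd, stability_series
from .structure_io import Structure, extract_corrin, read_structure

__all__ = ["run_pipeline", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Invalid run configuration (reported before any computation)."""


_KNOWN_BLOCKS = {"structures", "transplant", "spectra", "stability", "mst", "conservation"}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("run config must be a YAML mapping")
    return cfg


def _validate(config: dict) -> None:
    unknown = set(config) - _KNOWN_BLOCKS - {"seed", "output_dir"}
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    if not set(config) & _KNOWN_BLOCKS:
        raise ConfigError("config requests no analysis blocks")
    for entry in config.get("structures", []):
        if "path" not in entry or "label" not in entry:
            raise ConfigError("each structures entry needs 'path' and 'label'")
    if "transplant" in config:
        t = config["transplant"]
        if "source" not in t or "targets" not in t:
            raise ConfigError("transplant block needs 'source' and 'targets'")
    if "mst" in config and "probe" not in config["mst"]:
        raise ConfigError("mst block needs the labelled-probe concentration 'probe'")


def _block(fn):
    try:
        return {"status": "ok", **fn()}
    except Exception as exc:  # per-block isolation is the contract
        return {"status": "error", "error": f"{type(exc).__name__}: {exc}"}


def run_pipeline(config: dict, base_dir: str | Path = ".") -> dict:
    """Execute the configured analysis blocks and return the report dict."""
    _validate(config)
    base = Path(base_dir)
    report: dict = {}
    structures: dict[str, Structure] = {}

    def resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else base / q

    if "structures" in config:
        blocks = {}
        for entry in config["structures"]:
            label = entry["label"]

            def analyse(entry=entry):
                st = read_structure(resolve(entry["path"]), entry.get("dialect", "auto"))
                st = st.reduce_altlocs()
                out: dict = {"n_atoms": len(st)}
                corrin = extract_corrin(st)
                out["corrin"] = axial_geometry(corrin).to_dict()
                out["disulfides"] = [
                    {"a": f"{ca}{ra}", "b": f"{cb}{rb}", "distance_A": round(d, 3)}
                    for (ca, ra), (cb, rb), d in find_disulfides(st)
                ]
                ligand_sel = entry.get("ligand")
                if ligand_sel is None and corrin.beta_ligand_atom is not None:
                    rid = corrin.beta_ligand_atom.residue_id
                    ligand = st.select(lambda a: a.residue_id == rid)
                else:
                    ligand = st.select(ligand_sel) if ligand_sel else None
                if ligand is not None and len(ligand):
                    protein = st.select(
                        lambda a: not a.is_water()
                        and a.residue_id not in {x.residue_id for x in ligand.atoms}
                        and a.residue_id != corrin.co.residue_id
                    )
                    waters = st.select("water")
                    contacts = polar_contacts(ligand, protein, waters)
                    out["polar_contacts"] = {
                        "total": len(contacts),
                        "direct": sum(c.kind == "direct" for c in contacts),
                        "water_mediated": sum(c.kind == "water_bridge" for c in contacts),
                    }
                domains = entry.get("domains")
                if domains:
                    corrin_res = {corrin.co.residue_id}
                    if corrin.beta_ligand_atom is not None:
                        corrin_res.add(corrin.beta_ligand_atom.residue_id)
                    cbl = st.select(lambda a: a.residue_id in corrin_res and not a.is_water())
                    parts = {"Cbl": cbl}
                    for name, sel in domains.items():
                        parts[name] = st.select(sel).select(lambda a: not a.is_water())
                    out["interfaces"] = interface_report(parts).to_dict()
                structures[label] = st
                return out

            blocks[label] = _block(analyse)
        report["structures"] = blocks

    if "transplant" in config:
        t = config["transplant"]

        def run_transplant():
            if t["source"] not in structures:
                raise ConfigError(f"transplant source {t['source']!r} not among analysed structures")
            src = structures[t["source"]]
            results = {}
            for label in t["targets"]:
                if label not in structures:
                    raise ConfigError(f"transplant target {label!r} not among analysed structures")
                rep = transplant(src, structures[label], soft_tol=t.get("soft_tol", 0.4))
                results[label] = rep.to_dict()
            return {"screens": results}

        report["transplant"] = _block(run_transplant)

    if "spectra" in config:
        s = config["spectra"]

        def run_spectra():
            ref = Spectrum.from_csv(resolve(s["reference"]))
            out = {}
            for p in s.get("others", []):
                other = Spectrum.from_csv(resolve(p))
                cmp_ = compare_spectra(ref, other)
                out[other.label] = {
                    "gamma_shift_nm": cmp_["gamma_shift_nm"],
                    "alphabeta_shift_nm": cmp_["alphabeta_shift_nm"],
                    "gamma_collapse_ratio": cmp_["gamma_collapse_ratio"],
                }
            return {"reference": ref.label, "comparisons": out}

        report["spectra"] = _block(run_spectra)

    if "stability" in config:
        s = config["stability"]

        def run_stability():
            ref = Spectrum.from_csv(resolve(s["reference"]))
            series = [(float(t_), Spectrum.from_csv(resolve(p))) for t_, p in s["series"]]
            return stability_series(ref, series)

        report["stability"] = _block(run_stability)

    if "mst" in config:
        m = config["mst"]

        def run_mst():
            df = pd.read_csv(resolve(m["curve_csv"]))
            conc = df.iloc[:, 0].to_numpy(dtype=float)
            y = df.iloc[:, 1].to_numpy(dtype=float)
            order = np.argsort(conc)
            curve = fit_kd(conc[order], y[order], probe_conc=float(m["probe"]))
            return curve.to_dict()

        report["mst"] = _block(run_mst)

    if "conservation" in config:
        c = config["conservation"]

        def run_conservation():
            seqs = read_fasta(resolve(c["fasta"]))
            ref_id = c["reference"]
            if ref_id not in seqs:
                raise ConfigError(f"reference sequence {ref_id!r} not in FASTA")
            homolog_ids = c.get("homologs") or [k for k in seqs if k != ref_id]
            identities = {}
            for hid in homolog_ids:
                pair = global_align(seqs[ref_id], seqs[hid], id_a=ref_id, id_b=hid)
                identities[hid] = percent_identity(pair)
            out = {"percent_identity": identities}
            if c.get("residues"):
                rows = map_conservation(
                    ref_id, seqs[ref_id],
                    {hid: seqs[hid] for hid in homolog_ids},
                    [int(r) for r in c["residues"]],
                )
                out["conservation"] = rows
            return out

        report["conservation"] = _block(run_conservation)

    body = {
        "provenance": {
            "config_sha256": hashlib.sha256(
                json.dumps(config, sort_keys=True, default=str).encode()
            ).hexdigest(),
            "package_version": __version__,
            "seed": config.get("seed", 0),
        },
        "blocks": report,
    }
    return {
        "generated_at": datetime.now(timezone.utc).isoformat(),
        **body,
    }


def all_blocks_ok(report: dict) -> bool:
    def ok(node) -> bool:
        if isinstance(node, dict):
            if node.get("status") == "error":
                return False
            return all(ok(v) for v in node.values())
        return True

    return ok(report["blocks"])
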