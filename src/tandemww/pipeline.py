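"""Configuration-driven orchestration of the analysis stages.

Three workflows mirror the study logic for a tandem-domain system:

``apo_validate``
    Validate a free-state ensemble against orthogonal solution data:
    per-domain RDC tensor fits (different tensors = interdomain mobility)
    and PRE profile back-calculation against observed ratios.

``complex_validate``
    Ensemble precision of a complex: backbone/heavy-atom RMSD over stated
    residue ranges, in both to-mean and pairwise conventions, plus the same
    optional RDC/PRE agreement checks.

``autoinhibition``
    Quantify intramolecular competition from paired ITC isotherms of the
    minimal and the N-terminally extended receptor: intrinsic Kd, apparent
    Kd and the inferred closed/open constant k_closed = Kd_app/Kd - 1.

Configs are flat ``key = value`` text with ``[stage]`` sections.  Stages
fail independently: a PRE failure never alters RDC outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import itc as itc_mod
from . import pre as pre_mod
from . import rdc as rdc_mod
from .ensemble import LabelSite, Selection, ensemble_rmsd, parse_selection, read_ensemble

log = logging.getLogger("tandemww.pipeline")

WORKFLOWS = ("apo_validate", "complex_validate", "autoinhibition")

_KNOWN_KEYS = {
    "": {"workflow", "seed", "outdir"},
    "ensemble": {"pdb", "selection", "chain"},
    "rdc": {"observed", "domain1", "domain2", "conformer"},
    "pre": {"observed", "site", "position_model", "tauc_ns", "r2_dia", "field_1h", "t_inept_ms"},
    "itc": {"reference", "extended"},
}

_FILE_KEYS = {("ensemble", "pdb"), ("rdc", "observed"), ("pre", "observed"),
              ("itc", "reference"), ("itc", "extended")}


@dataclass
class RunConfig:
    workflow: str
    seed: int = 0
    outdir: str = "tandemww_out"
    sections: dict[str, dict[str, str]] = field(default_factory=dict)

    @classmethod
    def parse(cls, path: str) -> "RunConfig":
        sections: dict[str, dict[str, str]] = {"": {}}
        current = ""
        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("[") and line.endswith("]"):
                current = line[1:-1].strip()
                sections.setdefault(current, {})
                continue
            key, sep, value = line.partition("=")
            if not sep:
                raise ValueError(f"malformed config line: {raw!r}")
            sections[current][key.strip()] = value.strip()
        top = sections.pop("")
        cfg = cls(
            workflow=top.get("workflow", ""),
            seed=int(top.get("seed", 0)),
            outdir=top.get("outdir", "tandemww_out"),
            sections=sections,
        )
        cfg.validate(base=Path(path).parent)
        return cfg

    def validate(self, base: Path | None = None) -> None:
        if self.workflow not in WORKFLOWS:
            raise ValueError(
                f"unknown workflow {self.workflow!r}; expected one of {WORKFLOWS}"
            )
        for section, keys in self.sections.items():
            if section not in _KNOWN_KEYS:
                raise ValueError(f"unknown config section [{section}]")
            unknown = set(keys) - _KNOWN_KEYS[section]
            if unknown:
                raise ValueError(
                    f"unknown keys {sorted(unknown)} in section [{section}]"
                )
            for key in keys:
                if (section, key) in _FILE_KEYS:
                    path = Path(keys[key])
                    if base is not None and not path.is_absolute():
                        path = base / path
                    if not path.exists():
                        raise FileNotFoundError(f"[{section}] {key}: {path} missing")
                    self.sections[section][key] = str(path)


def _setup_logging(outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    log.addHandler(handler)
    log.setLevel(logging.INFO)


def run(config: RunConfig) -> dict:
    """Execute the configured workflow; returns the summary dictionary.

    Per-stage tables are written under ``config.outdir`` together with a
    plain-text ``summary.txt``; stage errors are recorded and do not stop
    independent stages.
    """
    outdir = Path(config.outdir)
    _setup_logging(outdir)
    log.info("workflow=%s seed=%d", config.workflow, config.seed)
    summary: dict = {"workflow": config.workflow, "seed": config.seed, "errors": {}}

    ens = None
    if "ensemble" in config.sections:
        try:
            ens = read_ensemble(config.sections["ensemble"]["pdb"])
            summary["n_conformers"] = ens.n_conformers
        except Exception as err:
            summary["errors"]["ensemble"] = str(err)
            log.error("ensemble stage failed: %s", err)

    if config.workflow == "complex_validate" and ens is not None:
        try:
            sel = parse_selection(
                config.sections["ensemble"].get("selection", "A:1-99999")
            )
            rows = []
            for mode in ("to_mean", "pairwise"):
                bb, heavy = ensemble_rmsd(ens, sel, mode=mode)
                rows.append((mode, bb, heavy))
                summary[f"rmsd_{mode}_backbone"] = bb
                summary[f"rmsd_{mode}_heavy"] = heavy
            pd.DataFrame(
                rows, columns=["mode", "backbone_rmsd_A", "heavy_rmsd_A"]
            ).to_csv(outdir / "ensemble_rmsd.tsv", sep="\t", index=False)
        except Exception as err:
            summary["errors"]["rmsd"] = str(err)
            log.error("rmsd stage failed: %s", err)

    if config.workflow in ("apo_validate", "complex_validate"):
        if "rdc" in config.sections and ens is not None:
            try:
                sec = config.sections["rdc"]
                rdcs = rdc_mod.read_rdcs(sec["observed"])
                conformer = int(sec.get("conformer", 0))
                chain = config.sections.get("ensemble", {}).get("chain", "A")
                fits = {}
                for dom in ("domain1", "domain2"):
                    if dom not in sec:
                        continue
                    lo, _, hi = sec[dom].partition("-")
                    fit = rdc_mod.svd_fit(
                        ens, conformer, rdcs, [(int(lo), int(hi))], chain
                    )
                    fits[dom] = fit
                    summary[f"rdc_{dom}_da"] = fit.tensor.da
                    summary[f"rdc_{dom}_q"] = fit.q_factor
                if len(fits) == 2:
                    cmp = rdc_mod.compare_domain_tensors(
                        fits["domain1"], fits["domain2"]
                    )
                    summary["rdc_da_ratio"] = cmp["da_ratio"]
                    summary["rdc_axis_angles_deg"] = cmp["axis_angles_deg"]
                pd.DataFrame(
                    [
                        (d, f.tensor.da, f.tensor.rhombicity, f.q_factor, f.n_used)
                        for d, f in fits.items()
                    ],
                    columns=["domain", "da_hz", "rhombicity", "q_factor", "n_used"],
                ).to_csv(outdir / "rdc_fits.tsv", sep="\t", index=False)
            except Exception as err:
                summary["errors"]["rdc"] = str(err)
                log.error("rdc stage failed: %s", err)
        if "pre" in config.sections and ens is not None:
            try:
                sec = config.sections["pre"]
                site = LabelSite(
                    int(sec["site"]),
                    chain=config.sections.get("ensemble", {}).get("chain", "A"),
                    position_model=sec.get("position_model", "CB_point"),
                )
                params = pre_mod.PREParams(
                    tauc_ns=float(sec.get("tauc_ns", 5.0)),
                    r2_dia=float(sec.get("r2_dia", 50.0)),
                    field_1h=float(sec.get("field_1h", 600.0)),
                    t_inept_ms=float(sec.get("t_inept_ms", 10.0)),
                )
                profile = pre_mod.predict_profile(ens, site, params)
                profile.to_csv(outdir / "pre_predicted.tsv", sep="\t", index=False)
                obs = pre_mod.read_pre(sec["observed"])
                report = pre_mod.compare(obs, profile)
                summary["pre_rmsd"] = report["rmsd"]
                summary["pre_n_outside"] = report["n_outside"]
            except Exception as err:
                summary["errors"]["pre"] = str(err)
                log.error("pre stage failed: %s", err)

    if config.workflow == "autoinhibition":
        try:
            sec = config.sections["itc"]
            ref = itc_mod.fit_isotherm(itc_mod.read_itc(sec["reference"]))
            ext = itc_mod.fit_isotherm(itc_mod.read_itc(sec["extended"]))
            k_closed = ext.model.kd / ref.model.kd - 1.0
            summary["kd_intrinsic_um"] = ref.model.kd
            summary["kd_apparent_um"] = ext.model.kd
            summary["k_closed"] = k_closed
            pd.DataFrame(
                [
                    ("reference", ref.model.kd, ref.model.n_sites, ref.model.dh),
                    ("extended", ext.model.kd, ext.model.n_sites, ext.model.dh),
                ],
                columns=["experiment", "kd_um", "n_sites", "dh_kcal_mol"],
            ).to_csv(outdir / "itc_fits.tsv", sep="\t", index=False)
        except Exception as err:
            summary["errors"]["itc"] = str(err)
            log.error("itc stage failed: %s", err)

    lines = [f"{k} = {v}" for k, v in summary.items() if k != "errors"]
    for stage, err in summary["errors"].items():
        lines.append(f"ERROR {stage}: {err}")
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
    log.info("done; %d stage error(s)", len(summary["errors"]))
    return summary
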