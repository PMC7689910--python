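"""End-to-end orchestration: stages to a per-residue summary table.

A single YAML (or dict) config names the inputs per stage; stages are
independently optional and executed in dependency order.  The summary joins
CSP, SSP, temperature-coefficient class, relaxation rates, spectral-density
group and ensemble statistics into one row per residue — the machine-
readable analogue of a binding/structure/dynamics figure panel series.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import csp as csp_mod
from . import ensemble as ens_mod
from . import relaxation as relax_mod
from . import secondary_structure as ss_mod
from .core_io import (
    Sequence,
    SpectrometerContext,
    ValidationError,
    read_constraints_tsv,
    read_ensemble_pdb,
    read_peaklist_sparky,
    read_sequence_fasta,
    read_shift_table,
)
from .reference_data import default_random_coil_table

logger = logging.getLogger("fuzzynmr.pipeline")

__all__ = ["PipelineResult", "run_pipeline"]

DEFAULTS = {
    "alpha": 0.14,
    "csp_threshold": 0.15,
    "ssp_window": 5,
    "cluster_cutoff": 1.0,
    "hbond_cutoff": 3.5,
    "contact_cutoff": 4.5,
    "noe_bound": 5.0,
    "anchor_min_freq": 0.5,
}


@dataclass
class PipelineResult:
    summary: pd.DataFrame
    reports: dict
    manifest: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.summary.to_csv(out / "summary.tsv", sep="\t", index=False)
        for name, report in self.reports.items():
            if isinstance(report, pd.DataFrame):
                report.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(self.manifest, fh)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _check_numbering(summary_index: pd.Index, residues, stage: str) -> None:
    extra = sorted(set(int(r) for r in residues) - set(summary_index))
    if extra:
        raise ValidationError(
            f"stage {stage}: residues {extra} are outside the declared "
            f"sequence numbering (declare a per-input offset)"
        )


def run_pipeline(config: dict | str | Path) -> PipelineResult:
    """Execute the configured stages and join their per-residue outputs.

    Config keys (all stages optional): ``sequence`` (fasta, offset),
    ``csp`` (free, bound), ``ssp`` (free, bound), ``tempco`` (series),
    ``relaxation`` (t1, t2, noe_sat, noe_unsat, freq_1h), ``ensemble``
    (pdb, chain, partner_chains, anchors), ``constraints`` (tsv),
    ``parameters`` overriding the default thresholds.  Residue numbering
    inconsistencies across inputs are a hard error listing the mismatches.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    params = {**DEFAULTS, **config.get("parameters", {})}
    manifest: dict = {"parameters": dict(params), "inputs": {}}
    reports: dict = {}

    def note_input(stage, key, path):
        manifest["inputs"][f"{stage}.{key}"] = {
            "path": str(path), "sha256": _sha256(Path(path))
        }

    seq_cfg = config.get("sequence")
    if seq_cfg is None:
        raise ValidationError("config must declare a sequence stage")
    seq = read_sequence_fasta(seq_cfg["fasta"], offset=int(seq_cfg.get("offset", 1)))
    note_input("sequence", "fasta", seq_cfg["fasta"])
    summary = pd.DataFrame(
        {
            "residue_index": list(seq.numbering),
            "residue_type": list(seq.residues),
        }
    ).set_index("residue_index")

    if "csp" in config:
        cfg = config["csp"]
        free = read_shift_table(cfg["free"], state="free")
        bound = read_shift_table(cfg["bound"], state="bound")
        note_input("csp", "free", cfg["free"])
        note_input("csp", "bound", cfg["bound"])
        profile = csp_mod.classify_perturbed(
            csp_mod.cumulative_delta(free, bound, alpha=params["alpha"]),
            threshold=params["csp_threshold"],
        )
        df = profile.per_residue.set_index("residue_index")
        _check_numbering(summary.index, df.index, "csp")
        summary["delta_cum"] = df["delta_cum"]
        summary["perturbed"] = df["perturbed"].astype("boolean")
        summary["broadened"] = df["broadened"].astype("boolean")
        regions = csp_mod.contiguous_regions(profile, min_len=3)
        reports["csp"] = df.reset_index()
        reports["csp_regions"] = pd.DataFrame(regions, columns=["start", "end"])
        logger.info("csp: %d residues, perturbed regions %s", len(df), regions)

    if "ssp" in config:
        cfg = config["ssp"]
        rc = default_random_coil_table()
        for state in ("free", "bound"):
            if state not in cfg:
                continue
            table = read_shift_table(cfg[state], state=state)
            note_input("ssp", state, cfg[state])
            sec = ss_mod.secondary_shifts(table, seq, rc)
            prof = ss_mod.ssp_profile(sec, window=int(params["ssp_window"]))
            df = prof.per_residue.set_index("residue_index")
            _check_numbering(summary.index, df.index, "ssp")
            summary[f"ssp_{state}"] = df["ssp"]
            reports[f"ssp_{state}"] = df.reset_index()

    if "tempco" in config:
        cfg = config["tempco"]
        series = []
        for item in cfg["series"]:
            pl = read_peaklist_sparky(
                item["path"], condition={"temperature": float(item["temperature"])}
            )
            note_input("tempco", f"T{item['temperature']}", item["path"])
            series.append(pl)
        prof = ss_mod.temp_coefficients(series)
        df = prof.per_residue.set_index("residue_index")
        _check_numbering(summary.index, df.index, "tempco")
        summary["tempco_ppb_per_K"] = df["slope_ppb_per_K"]
        summary["tempco_class"] = df["tc_class"]
        reports["tempco"] = df.reset_index()

    if "relaxation" in config:
        cfg = config["relaxation"]
        ctx = SpectrometerContext(freq_1H=float(cfg.get("freq_1h", 700.17)))
        t1 = relax_mod.DecaySeries.from_tsv(cfg["t1"], "T1")
        t2 = relax_mod.DecaySeries.from_tsv(cfg["t2"], "T2")
        for key in ("t1", "t2", "noe_sat", "noe_unsat"):
            note_input("relaxation", key, cfg[key])
        fit1 = relax_mod.fit_exponential_decay(t1).set_index("residue_index")
        fit2 = relax_mod.fit_exponential_decay(t2).set_index("residue_index")
        sat = pd.read_csv(cfg["noe_sat"], sep=r"\s+", comment="#",
                          names=["residue_index", "intensity"])
        unsat = pd.read_csv(cfg["noe_unsat"], sep=r"\s+", comment="#",
                            names=["residue_index", "intensity"])
        noe = relax_mod.het_noe(sat, unsat).set_index("residue_index")
        common = fit1.index.intersection(fit2.index).intersection(noe.index)
        _check_numbering(summary.index, common, "relaxation")
        rec = relax_mod.RelaxationRecord(
            per_residue=pd.DataFrame(
                {
                    "residue_index": common,
                    "R1": fit1.loc[common, "rate"],
                    "sigma_R1": fit1.loc[common, "sigma"],
                    "R2": fit2.loc[common, "rate"],
                    "sigma_R2": fit2.loc[common, "sigma"],
                    "hetNOE": noe.loc[common, "hetNOE"],
                    "sigma_hetNOE": 0.02,
                }
            ).reset_index(drop=True),
            context=ctx,
        )
        triples = relax_mod.group_residues(
            relax_mod.reduced_spectral_density(rec, n_mc=0)
        )
        df = triples.per_residue.set_index("residue_index")
        summary["R1"] = rec.per_residue.set_index("residue_index")["R1"]
        summary["R2"] = rec.per_residue.set_index("residue_index")["R2"]
        summary["hetNOE"] = rec.per_residue.set_index("residue_index")["hetNOE"]
        summary["J0"] = df["J0"]
        summary["JwN"] = df["JwN"]
        summary["jgroup"] = df["group"]
        reports["relaxation"] = rec.per_residue
        reports["spectral_density"] = df.reset_index()

    if "ensemble" in config:
        cfg = config["ensemble"]
        ens = read_ensemble_pdb(cfg["pdb"])
        note_input("ensemble", "pdb", cfg["pdb"])
        chain = cfg.get("chain", "P")
        _check_numbering(
            summary.index,
            ens.atoms.loc[ens.atoms.chain == chain, "residue_index"].unique(),
            "ensemble",
        )
        mc_mask = ens.main_chain_mask(chain=chain)
        aligned, _ = ens_mod.superpose(ens, selection=mc_mask)
        hf = ens_mod.helix_fraction(aligned, chain=chain).set_index("residue_index")
        summary["helix_fraction"] = hf["helix_fraction"]
        bf = ens_mod.bfactors(aligned.subset(aligned.select(chain=chain)))
        summary["B"] = bf.set_index("residue_index")["B"]
        cluster = ens_mod.gromos_cluster(
            aligned, selection=mc_mask, cutoff=float(params["cluster_cutoff"])
        )
        reports["clusters"] = pd.DataFrame(
            {"snapshot": np.arange(aligned.n_models),
             "cluster": cluster.membership}
        )
        manifest["cluster_sizes"] = cluster.sizes
        partner = cfg.get("partner_chains", ["A", "B"])
        try:
            contacts = ens_mod.residue_contacts(
                aligned, chain, partner, cutoff=float(params["contact_cutoff"])
            )
            anchor_freq = (
                contacts.groupby("residue_a")["frequency"].max()
                if len(contacts)
                else pd.Series(dtype=float)
            )
            summary["anchor_flag"] = pd.array(
                [
                    bool(anchor_freq.get(res, 0.0) >= params["anchor_min_freq"])
                    for res in summary.index
                ],
                dtype="boolean",
            )
            reports["contacts"] = contacts
        except ValidationError:
            logger.info("ensemble: no partner chains found; contacts skipped")
        if "constraints" in config:
            constraints = read_constraints_tsv(config["constraints"]["tsv"])
            note_input("constraints", "tsv", config["constraints"]["tsv"])
            reports["noe_check"] = ens_mod.check_noe_constraints(aligned, constraints)

    summary = summary.reset_index()
    manifest["n_residues"] = len(summary)
    manifest["stages"] = sorted(
        k for k in config if k in
        ("csp", "ssp", "tempco", "relaxation", "ensemble", "constraints")
    )
    return PipelineResult(summary=summary, reports=reports, manifest=manifest)
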