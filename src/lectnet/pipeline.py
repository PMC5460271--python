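"""Pipeline orchestration: one YAML config drives every analysis stage.

Stages (each optional, driven by which inputs the config names):

* ``classify`` — monomer/complex SASA classification + interface contact pairs
* ``network``  — trajectory -> dynamical network -> centrality metrics
* ``conserve`` — alignment conservation grades
* ``dca``      — mean-field DCA / direct information
* ``hp``       — hydrophobic-polar pattern resampling

Outputs are TSV/JSON files stamped with a config hash and the seed; rerunning
with an identical config reproduces them byte for byte.  With ``resume``,
stages whose outputs already exist are skipped.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import dca as dca_mod
from . import graphmetrics, network, seqanalysis, structure

__all__ = ["RunConfig", "ConfigError", "run_pipeline", "write_report"]


class ConfigError(ValueError):
    """Raised when a run configuration fails validation (CLI exit code 2)."""


_DEFAULTS = {
    "exposed_threshold": 0.20,
    "contact_cutoff": 4.0,
    "ligand_cutoff": 3.9,
    "ligand_names": ["MAN"],
    "persistence_cutoff": 4.5,
    "persistence_fraction": 0.75,
    "frame_start": 0,
    "betweenness_z_cutoff": 1.5,
    "dpl_z_cutoff": 1.0,
    "pseudocount": 0.5,
    "identity_threshold": 0.8,
    "max_gap_fraction": 0.5,
    "di_threshold": 0.8,
    "min_separation": 2,
    "hp_positions": None,  # [col_single, col_double] 0-based alignment columns
    "n_single": 31,
    "n_double": 11,
    "hp_reps": 5,
    "seed": 0,
}

_RANGES = {
    "exposed_threshold": (0.0, 1.0),
    "contact_cutoff": (0.0, 100.0),
    "ligand_cutoff": (0.0, 100.0),
    "persistence_cutoff": (0.0, 100.0),
    "persistence_fraction": (0.0, 1.0),
    "identity_threshold": (0.0, 1.0),
    "max_gap_fraction": (0.0, 1.0),
    "pseudocount": (0.0, 1e6),
    "di_threshold": (0.0, 1e6),
}


@dataclass
class RunConfig:
    """Validated pipeline configuration (paper defaults pre-filled)."""

    output_dir: str
    monomer_pdb: str | None = None
    monomer_pdb_b: str | None = None
    complex_pdb: str | None = None
    chain_a: str = "A"
    chain_b: str = "B"
    trajectory_pdb: str | None = None
    msa_fasta: str | None = None
    msa_single_fasta: str | None = None
    msa_double_fasta: str | None = None
    params: dict = field(default_factory=dict)
    resume: bool = False

    def __post_init__(self) -> None:
        merged = dict(_DEFAULTS)
        unknown = set(self.params) - set(_DEFAULTS)
        if unknown:
            raise ConfigError(f"unknown parameters: {sorted(unknown)}")
        merged.update(self.params)
        for key, (lo, hi) in _RANGES.items():
            v = merged[key]
            if not (lo <= float(v) <= hi):
                raise ConfigError(f"parameter {key}={v} outside [{lo}, {hi}]")
        if merged["hp_positions"] is not None and len(merged["hp_positions"]) != 2:
            raise ConfigError("hp_positions must name exactly two columns")
        self.params = merged
        for name in (
            "monomer_pdb",
            "monomer_pdb_b",
            "complex_pdb",
            "trajectory_pdb",
            "msa_fasta",
            "msa_single_fasta",
            "msa_double_fasta",
        ):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"input file for {name} does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "output_dir" not in raw:
            raise ConfigError("config must name output_dir")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def hash(self) -> str:
        blob = json.dumps(
            {k: v for k, v in self.__dict__.items() if k != "resume"},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write(path: Path, text: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(text)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all configured stages in dependency order; return the manifest."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": cfg.hash(),
        "seed": cfg.params["seed"],
        "package_version": __import__("lectnet").__version__,
        "parameters": {k: v for k, v in cfg.params.items()},
        "stages": {},
    }
    p = cfg.params

    def stage_done(*files: str) -> bool:
        return cfg.resume and all((out / f).exists() for f in files)

    if cfg.complex_pdb:
        t0 = time.perf_counter()
        files = ("classification.tsv", "contacts.tsv")
        if not stage_done(*files):
            try:
                _stage_classify(cfg, out)
            except Exception as exc:
                raise RuntimeError(
                    f"stage classify failed on {cfg.complex_pdb}: {exc}"
                ) from exc
        manifest["stages"]["classify"] = {
            "outputs": list(files),
            "seconds": round(time.perf_counter() - t0, 3),
        }

    if cfg.trajectory_pdb:
        t0 = time.perf_counter()
        files = ("metrics.tsv", "network.json", "network_summary.json")
        if not stage_done(*files):
            try:
                _stage_network(cfg, out)
            except Exception as exc:
                raise RuntimeError(
                    f"stage network failed on {cfg.trajectory_pdb}: {exc}"
                ) from exc
        manifest["stages"]["network"] = {
            "outputs": list(files),
            "seconds": round(time.perf_counter() - t0, 3),
        }

    if cfg.msa_fasta:
        t0 = time.perf_counter()
        files = ("conservation.tsv", "di_table.tsv", "dca_manifest.json")
        if not stage_done(*files):
            try:
                _stage_sequence(cfg, out)
            except Exception as exc:
                raise RuntimeError(f"stage dca failed on {cfg.msa_fasta}: {exc}") from exc
        manifest["stages"]["dca"] = {
            "outputs": list(files),
            "seconds": round(time.perf_counter() - t0, 3),
        }

    if cfg.msa_single_fasta and cfg.msa_double_fasta and p["hp_positions"]:
        t0 = time.perf_counter()
        files = ("hp_patterns.tsv",)
        if not stage_done(*files):
            try:
                _stage_hp(cfg, out)
            except Exception as exc:
                raise RuntimeError(f"stage hp failed: {exc}") from exc
        manifest["stages"]["hp"] = {
            "outputs": list(files),
            "seconds": round(time.perf_counter() - t0, 3),
        }

    _write(out / "run_manifest.json", json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _stage_classify(cfg: RunConfig, out: Path) -> None:
    p = cfg.params
    complex_s = structure.read_structure(Path(cfg.complex_pdb).read_text())
    pairs = structure.find_interface_pairs(
        complex_s, cfg.chain_a, cfg.chain_b, cutoff=p["contact_cutoff"]
    )
    _write(out / "contacts.tsv", structure.contact_table(pairs).to_csv(sep="\t", index=False))

    if not cfg.monomer_pdb:
        _write(out / "classification.tsv", "")
        return
    monomer = structure.read_structure(Path(cfg.monomer_pdb).read_text())
    monomers = [monomer]
    if cfg.monomer_pdb_b:
        monomers.append(structure.read_structure(Path(cfg.monomer_pdb_b).read_text()))
    try:
        ligand = structure.find_ligand_contacts(
            complex_s, p["ligand_names"], cutoff=p["ligand_cutoff"]
        )
    except structure.StructureError:
        ligand = set()
    complex_sasa = structure.compute_sasa(complex_s)
    comp_map = complex_sasa.as_dict()
    tables = []
    for mono in monomers:
        mono_sasa = structure.compute_sasa(mono)
        sub = structure.SasaProfile(
            mono_sasa.residues,
            complex_sasa.absolute[[complex_sasa.residues.index(r) for r in mono_sasa.residues]],
            [comp_map[r][1] for r in mono_sasa.residues],
            complex_sasa.probe_radius,
        )
        cls = structure.classify_residues(
            mono_sasa, sub, exposed_threshold=p["exposed_threshold"], ligand_contacts=ligand
        )
        tables.append(structure.classification_table(cls))
    import pandas as pd

    _write(
        out / "classification.tsv",
        pd.concat(tables, ignore_index=True).to_csv(sep="\t", index=False),
    )


def _stage_network(cfg: RunConfig, out: Path) -> None:
    p = cfg.params
    traj = network.read_trajectory(Path(cfg.trajectory_pdb).read_text())
    g = network.network_from_trajectory(
        traj,
        contact_cutoff=p["persistence_cutoff"],
        min_fraction=p["persistence_fraction"],
        frame_start=p["frame_start"],
    )
    table, summary = graphmetrics.network_metrics(
        g,
        betweenness_z_cutoff=p["betweenness_z_cutoff"],
        dpl_z_cutoff=p["dpl_z_cutoff"],
    )
    _write(out / "network.json", network.network_to_json(g))
    _write(out / "metrics.tsv", table.to_csv(sep="\t", index=False))
    _write(out / "network_summary.json", json.dumps(summary, indent=1, sort_keys=True))


def _stage_sequence(cfg: RunConfig, out: Path) -> None:
    p = cfg.params
    aln = dca_mod.read_alignment(Path(cfg.msa_fasta).read_text())
    profile = seqanalysis.conservation_grades(aln)
    _write(out / "conservation.tsv", profile.table().to_csv(sep="\t", index=False))
    table, run_manifest = dca_mod.run_dca(
        aln,
        pseudocount=p["pseudocount"],
        identity_threshold=p["identity_threshold"],
        max_gap_fraction=p["max_gap_fraction"],
        di_threshold=p["di_threshold"],
        min_separation=p["min_separation"],
    )
    _write(out / "di_table.tsv", table.to_csv(sep="\t", index=False))
    _write(out / "dca_manifest.json", json.dumps(run_manifest, indent=1, sort_keys=True))


def _stage_hp(cfg: RunConfig, out: Path) -> None:
    p = cfg.params
    single = dca_mod.read_alignment(Path(cfg.msa_single_fasta).read_text())
    double = dca_mod.read_alignment(Path(cfg.msa_double_fasta).read_text())
    res_s, res_d = seqanalysis.hp_pattern_analysis(
        single,
        double,
        tuple(p["hp_positions"]),
        n_single=p["n_single"],
        n_double=p["n_double"],
        reps=p["hp_reps"],
        seed=p["seed"],
    )
    import pandas as pd

    ts = res_s.counts.assign(domain_class="single")
    td = res_d.counts.assign(domain_class="double")
    _write(out / "hp_patterns.tsv", pd.concat([ts, td], ignore_index=True).to_csv(sep="\t", index=False))


def write_report(output_dir: str | Path) -> str:
    """Human-readable summary of whatever stage outputs exist in a run directory."""
    import pandas as pd

    out = Path(output_dir)
    lines = ["# lectnet run report", ""]
    manifest_path = out / "run_manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        lines.append(
            f"config hash {manifest['config_hash']}, seed {manifest['seed']}, "
            f"package version {manifest['package_version']}"
        )
        lines.append("")

    cls_path = out / "classification.tsv"
    if cls_path.exists() and cls_path.stat().st_size:
        cls = pd.read_csv(cls_path, sep="\t")
        counts = cls["category"].value_counts().to_dict()
        lines.append("## Residue classification")
        lines.append(", ".join(f"{k}: {v}" for k, v in sorted(counts.items())))
        lines.append("")

    metrics_path = out / "metrics.tsv"
    if metrics_path.exists():
        m = pd.read_csv(metrics_path, sep="\t")
        lines.append("## Network metrics")
        summary_path = out / "network_summary.json"
        if summary_path.exists():
            s = json.loads(summary_path.read_text())
            lines.append(
                f"CPL {s['cpl']:.4f} over {s['n_nodes']} nodes / {s['n_edges']} edges "
                f"({s['n_components']} component(s))"
            )
        flagged_b = m[m["betweenness_flag"]].sort_values("betweenness_z", ascending=False)
        lines.append("high-betweenness residues:")
        for _, row in flagged_b.iterrows():
            lines.append(f"  {row['node']}  z = {row['betweenness_z']:.2f}")
        flagged_d = m[m["dpl_flag"]].sort_values("dpl_z", ascending=False)
        lines.append("high-DPL residues:")
        for _, row in flagged_d.iterrows():
            lines.append(f"  {row['node']}  z = {row['dpl_z']:.2f}")
        tiers = m["closeness_tier"].value_counts().to_dict()
        lines.append(
            "closeness tiers: "
            + ", ".join(f"{k}: {tiers.get(k, 0)}" for k in ("high", "intermediate", "low"))
        )
        lines.append("")

    di_path = out / "di_table.tsv"
    if di_path.exists():
        di = pd.read_csv(di_path, sep="\t")
        lines.append("## Direct coupling analysis")
        flagged = di[di["flagged"]]
        lines.append(f"{len(flagged)} column pair(s) above the DI threshold:")
        for _, row in flagged.head(20).iterrows():
            lines.append(
                f"  columns {int(row['orig_i'])}-{int(row['orig_j'])}  DI = {row['di']:.3f}"
            )
        lines.append("")

    hp_path = out / "hp_patterns.tsv"
    if hp_path.exists():
        hp = pd.read_csv(hp_path, sep="\t")
        lines.append("## Hydrophobic-polar interaction patterns")
        for cls_name, grp in hp.groupby("domain_class"):
            total = grp[["polar_polar", "polar_hydrophobic", "hydrophobic_hydrophobic"]].sum(axis=1)
            fr = grp[["polar_polar", "polar_hydrophobic", "hydrophobic_hydrophobic"]].div(total, axis=0).mean()
            lines.append(
                f"{cls_name}-domain: PP {fr['polar_polar']:.2f}, "
                f"PH {fr['polar_hydrophobic']:.2f}, HH {fr['hydrophobic_hydrophobic']:.2f} "
                f"(mean over {len(grp)} replicates)"
            )
        lines.append("")

    if len(lines) <= 2:
        raise ValueError(f"no stage outputs found in {out}")
    text = "\n".join(lines)
    (out / "report.md").write_text(text)
    return text
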