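"""File formats, run configuration and the end-to-end pipeline driver.

Trajectories are written as multi-MODEL PDB (via gemmi; 1e-3 Angstrom
format precision, 3-character residue names) or as multi-frame XYZ with
extended atom names ``SPECIES.MOLID.LABEL`` at 1e-6 Angstrom precision.
Tabular data travel as comma-separated UTF-8 CSV with a header row and
'.' decimals; every generated artifact gets a JSON sidecar echoing the
generator parameters and seed.  ``run_pipeline`` chains the stages
synth -> analyze -> fit -> kinetics from a single validated configuration
and one seed, and writes a manifest with SHA-256 checksums so identical
configurations reproduce byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Literal, Sequence

import gemmi
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import oxidation_kinetics as ox
from . import synthetic_data as synth
from . import trajectory_analysis as ta
from .droplet import SPECIES_MASSES, DropletFrame, DropletTrajectory
from .emulsion_model import KobsSeries, distribution_table, fit_partition
from .errors import FormatError, MappingError
from .oxidation_kinetics import OxidationCurve

__all__ = [
    "RunConfig",
    "read_frames",
    "write_frames",
    "read_curve_csv",
    "write_curve_csv",
    "run_pipeline",
    "DEFAULT_SPECIES_MAP",
]

# PDB residue names are 3 characters; map both directions
_PDB_RESNAME = {"OLE": "OLE", "TW80": "TW8", "GAL": "GAL", "HOH": "HOH"}
DEFAULT_SPECIES_MAP: dict[str, str] = {
    "OLE": "OLE", "TW8": "TW80", "TW80": "TW80", "GAL": "GAL",
    "HOH": "HOH", "WAT": "HOH", "SOL": "HOH",
}
_ELEMENT = {"O": "O", "C": "C"}


def _atom_element(species: str, label: str) -> str:
    if label.startswith("O") or label in ("EOH",):
        return "O"
    return "C"


# --------------------------------------------------------------------------
# PDB
# --------------------------------------------------------------------------

def _write_pdb(traj: DropletTrajectory, path: Path) -> None:
    st = gemmi.Structure()
    st.name = "droplet"
    for fi, fr in enumerate(traj):
        model = gemmi.Model(str(fi + 1))
        chain = gemmi.Chain("A")
        prev_key = None
        res = None
        seq = 0
        for i in range(fr.n_atoms):
            sp, mol, lbl = fr.species[i], int(fr.mol_id[i]), fr.label[i]
            key = (sp, mol)
            if key != prev_key:
                if res is not None:
                    chain.add_residue(res)
                seq += 1
                res = gemmi.Residue()
                res.name = _PDB_RESNAME.get(sp, sp[:3])
                res.seqid = gemmi.SeqId(((seq - 1) % 9999) + 1, " ")
                prev_key = key
            at = gemmi.Atom()
            at.name = lbl
            at.element = gemmi.Element(_atom_element(sp, lbl))
            x, y, z = fr.coords[i]
            at.pos = gemmi.Position(float(x), float(y), float(z))
            res.add_atom(at)
        if res is not None:
            chain.add_residue(res)
        model.add_chain(chain)
        st.add_model(model)
    st.write_pdb(str(path))


def _read_pdb(path: Path, mapping: dict[str, str]) -> DropletTrajectory:
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse PDB {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"no MODEL records in {path}")
    frames = []
    for model in st:
        species, mol_id, label, coords, mass = [], [], [], [], []
        mol = -1
        for chain in model:
            for res in chain:
                mol += 1
                if res.name not in mapping:
                    raise MappingError(
                        f"residue name {res.name!r} not in the species mapping")
                sp = mapping[res.name]
                for at in res:
                    key = (sp, at.name)
                    if key not in SPECIES_MASSES:
                        raise MappingError(
                            f"unknown atom label {at.name!r} for species {sp!r}")
                    species.append(sp)
                    mol_id.append(mol)
                    label.append(at.name)
                    coords.append([at.pos.x, at.pos.y, at.pos.z])
                    mass.append(SPECIES_MASSES[key])
        frames.append(DropletFrame(np.array(species, dtype=object), np.array(mol_id),
                                   np.array(label, dtype=object), np.array(coords),
                                   np.array(mass)))
    return DropletTrajectory(frames)


# --------------------------------------------------------------------------
# multi-frame XYZ
# --------------------------------------------------------------------------

def _write_xyz(traj: DropletTrajectory, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for fi, fr in enumerate(traj):
            fh.write(f"{fr.n_atoms}\n")
            fh.write(f"frame {fi}\n")
            for sp, mol, lbl, (x, y, z) in zip(fr.species, fr.mol_id, fr.label, fr.coords):
                fh.write(f"{sp}.{mol}.{lbl} {x:.6f} {y:.6f} {z:.6f}\n")


def _read_xyz(path: Path, mapping: dict[str, str]) -> DropletTrajectory:
    frames = []
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise FormatError(f"{path}:{i + 1}: expected atom count, got "
                              f"{lines[i].strip()!r}") from exc
        if i + 1 >= len(lines):
            raise FormatError(f"{path}:{i + 2}: truncated frame (missing comment line)")
        species, mol_id, label, coords, mass = [], [], [], [], []
        for j in range(n):
            ln = i + 2 + j
            if ln >= len(lines):
                raise FormatError(f"{path}:{ln + 1}: truncated frame")
            parts = lines[ln].split()
            if len(parts) != 4:
                raise FormatError(f"{path}:{ln + 1}: expected 'NAME x y z'")
            name = parts[0].split(".")
            if len(name) != 3:
                raise FormatError(
                    f"{path}:{ln + 1}: atom name must be SPECIES.MOLID.LABEL")
            sp_raw, mol, lbl = name
            if sp_raw not in mapping:
                raise MappingError(f"species tag {sp_raw!r} not in the mapping")
            sp = mapping[sp_raw]
            if (sp, lbl) not in SPECIES_MASSES:
                raise MappingError(f"unknown atom label {lbl!r} for species {sp!r}")
            species.append(sp)
            mol_id.append(int(mol))
            label.append(lbl)
            coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
            mass.append(SPECIES_MASSES[(sp, lbl)])
        frames.append(DropletFrame(np.array(species, dtype=object), np.array(mol_id),
                                   np.array(label, dtype=object), np.array(coords),
                                   np.array(mass)))
        i += 2 + n
    if not frames:
        raise FormatError(f"{path}: no frames found")
    return DropletTrajectory(frames)


def load_species_mapping(path: str | Path | None) -> dict[str, str]:
    """Species mapping from a YAML file ({resname_or_tag: species}), merged
    over the built-in defaults so converted real MD output can be analyzed."""
    mapping = dict(DEFAULT_SPECIES_MAP)
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise MappingError("species mapping file must contain a mapping")
        mapping.update({str(k): str(v) for k, v in user.items()})
    return mapping


def write_frames(traj: DropletTrajectory, path: str | Path,
                 format: Literal["pdb", "xyz-multi"] | None = None) -> None:
    """Write a trajectory as multi-MODEL PDB or multi-frame XYZ."""
    path = Path(path)
    fmt = format or ("pdb" if path.suffix.lower() == ".pdb" else "xyz-multi")
    if fmt == "pdb":
        _write_pdb(traj, path)
    elif fmt == "xyz-multi":
        _write_xyz(traj, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_frames(path: str | Path,
                format: Literal["pdb", "xyz-multi"] | None = None,
                mapping: dict[str, str] | str | Path | None = None) -> DropletTrajectory:
    """Read a trajectory; format inferred from the extension when omitted."""
    path = Path(path)
    fmt = format or ("pdb" if path.suffix.lower() == ".pdb" else "xyz-multi")
    if isinstance(mapping, (str, Path)):
        mapping = load_species_mapping(mapping)
    elif mapping is None:
        mapping = dict(DEFAULT_SPECIES_MAP)
    if fmt == "pdb":
        return _read_pdb(path, mapping)
    if fmt == "xyz-multi":
        return _read_xyz(path, mapping)
    raise ValueError(f"unknown format {fmt!r}")


# --------------------------------------------------------------------------
# curve CSV
# --------------------------------------------------------------------------

def write_curve_csv(curve: OxidationCurve, path: str | Path) -> None:
    pd.DataFrame({"time_h": curve.time, "signal": curve.signal,
                  "label": curve.label}).to_csv(path, index=False)


def read_curve_csv(path: str | Path) -> OxidationCurve:
    df = pd.read_csv(path)
    for col in ("time_h", "signal"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    label = str(df["label"].iloc[0]) if "label" in df.columns else ""
    return OxidationCurve(df["time_h"].to_numpy(), df["signal"].to_numpy(), label)


def _write_json(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

class EmulsionSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    ao_total: float = 1e-4
    phi_oil: float = 0.10
    phi_list: list[float] = Field(default_factory=lambda: list(np.linspace(0.005, 0.04, 8)))
    true_p_wi: float = 93.0
    true_k_i: float = 100.0
    noise_cv: float = 0.05
    method: Literal["nonlinear", "reciprocal-linear"] = "nonlinear"

    @model_validator(mode="after")
    def _check(self) -> "EmulsionSection":
        for phi in self.phi_list:
            if phi <= 0 or self.phi_oil + phi >= 1:
                raise ValueError(f"phi_oil + phi_I must lie in (0, 1); got phi_I={phi}")
        return self


class DropletSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_oleic: int = 200
    n_surfactant: int = 20
    n_antioxidant: int = 8
    n_water: int = 2000  # scaled-down default for pipeline demos
    core_radius: float = 20.0
    interface_thickness: float = 17.0
    water_extent: float = 23.0
    radial_mean: float = 31.0
    radial_sd: float = 6.0
    n_frames: int = 50


class AnalysisSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    radial_bin_width: float = 1.0
    angle_bin_width: float = 3.0
    core_cut: float = 0.95
    bulk_cut: float = 0.90


class OxidationSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    r_init: float = 6.7e-6
    k_prop: float = 200.0
    k_term: float = 1.0e6
    k_inh: float = 1.0e7
    rh0: float = 0.32
    aoh0: float = 1.0e-4
    n_stoich: float = 2.0
    t_max: float = 80.0
    n_points: int = 120
    min_segment: int = 3


class RunConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    stages: list[Literal["synth", "analyze", "fit", "kinetics"]] = Field(
        default_factory=lambda: ["synth", "analyze", "fit", "kinetics"])
    emulsion: EmulsionSection = Field(default_factory=EmulsionSection)
    droplet: DropletSection = Field(default_factory=DropletSection)
    analysis: AnalysisSection = Field(default_factory=AnalysisSection)
    oxidation: OxidationSection = Field(default_factory=OxidationSection)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run the requested stages and write a checksummed manifest.

    Stage order is synth -> analyze -> fit -> kinetics; analysis stages read
    the files the synth stage wrote into ``out_dir``, so configurations are
    self-contained and a fixed (config, seed) pair reproduces every output
    byte for byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config
    seed = cfg.seed
    artifacts: dict[str, str] = {}
    stages_run: list[str] = []

    def record(name: str, path: Path) -> None:
        artifacts[name] = str(path.name)

    if "synth" in cfg.stages:
        d = cfg.droplet
        spec = synth.SpeciesSpec(
            n_oleic=d.n_oleic, n_surfactant=d.n_surfactant,
            n_antioxidant=d.n_antioxidant, n_water=d.n_water,
            core_radius=d.core_radius, interface_thickness=d.interface_thickness,
            water_extent=d.water_extent,
            antioxidant_radial_law=synth.Law.gaussian(d.radial_mean, d.radial_sd),
            seed=seed)
        traj = synth.sample_trajectory(spec, d.n_frames)
        write_frames(traj, out / "trajectory.xyz", "xyz-multi")
        record("trajectory", out / "trajectory.xyz")

        e = cfg.emulsion
        series = synth.generate_kobs_series(
            e.true_p_wi, e.true_k_i, e.ao_total, e.phi_oil, e.phi_list,
            e.noise_cv, seed)
        series.to_frame().to_csv(out / "kobs.csv", index=False)
        record("kobs", out / "kobs.csv")

        o = cfg.oxidation
        t_grid = np.linspace(0.0, o.t_max, o.n_points)
        params_ao = synth.KineticSchemeParams(
            r_init=o.r_init, k_prop=o.k_prop, k_term=o.k_term, k_inh=o.k_inh,
            rh0=o.rh0, aoh0=o.aoh0, n_stoich=o.n_stoich)
        params_ctrl = dataclasses.replace(params_ao, aoh0=0.0)
        write_curve_csv(synth.simulate_oxidation(params_ao, t_grid),
                        out / "oxidation_antioxidant.csv")
        write_curve_csv(synth.simulate_oxidation(params_ctrl, t_grid),
                        out / "oxidation_control.csv")
        record("oxidation_antioxidant", out / "oxidation_antioxidant.csv")
        record("oxidation_control", out / "oxidation_control.csv")
        _write_json({"seed": seed, "spec": dataclasses.asdict(spec) | {
            "antioxidant_radial_law": dataclasses.asdict(spec.antioxidant_radial_law),
            "antioxidant_angle_laws": None},
            "emulsion": e.model_dump(), "oxidation": o.model_dump()},
            out / "generator_params.json")
        record("generator_params", out / "generator_params.json")
        stages_run.append("synth")

    if "analyze" in cfg.stages:
        a = cfg.analysis
        traj = read_frames(out / "trajectory.xyz", "xyz-multi")
        profiles = {sp: ta.radial_profile(traj, sp, a.radial_bin_width)
                    for sp in ("OLE", "GAL", "HOH")}
        prof_rows = []
        for sp, prof in profiles.items():
            df = prof.to_frame()
            df.insert(0, "species", sp)
            prof_rows.append(df)
        pd.concat(prof_rows).to_csv(out / "radial_profiles.csv", index=False)
        record("radial_profiles", out / "radial_profiles.csv")

        bounds = ta.estimate_regions(profiles["OLE"], profiles["HOH"],
                                     a.core_cut, a.bulk_cut)
        pcts = ta.region_fractions(traj, bounds)
        _write_json({"core_radius_A": bounds.core_radius,
                     "interface_thickness_A": bounds.interface_thickness,
                     "water_onset_A": bounds.water_onset,
                     "pct_oil": pcts[0], "pct_interfacial": pcts[1],
                     "pct_aqueous": pcts[2]}, out / "regions.json")
        record("regions", out / "regions.json")

        ta.oxygen_distances(traj).to_csv(out / "oxygen_distances.csv")
        record("oxygen_distances", out / "oxygen_distances.csv")

        angle_rows = []
        for name in ("alpha", "beta", "gamma"):
            dist = ta.angle_distribution(traj, name, a.angle_bin_width)
            df = dist.to_frame()
            df.insert(0, "angle", name)
            angle_rows.append(df)
        pd.concat(angle_rows).to_csv(out / "angle_distributions.csv", index=False)
        record("angle_distributions", out / "angle_distributions.csv")

        joint = ta.joint_angle_distribution(traj, a.angle_bin_width)
        _write_json({"maxima": [list(m) for m in joint.maxima[:10]]},
                    out / "joint_angle_maxima.json")
        record("joint_angle_maxima", out / "joint_angle_maxima.json")
        stages_run.append("analyze")

    if "fit" in cfg.stages:
        e = cfg.emulsion
        series = KobsSeries.from_csv(out / "kobs.csv", e.ao_total, e.phi_oil)
        fit = fit_partition(series, e.method, restart_seed=seed)
        _write_json(fit.to_dict(), out / "partition_fit.json")
        record("partition_fit", out / "partition_fit.json")
        distribution_table(fit.p_wi, e.ao_total, e.phi_oil, e.phi_list).to_csv(
            out / "distribution_table.csv", index=False)
        record("distribution_table", out / "distribution_table.csv")
        stages_run.append("fit")

    if "kinetics" in cfg.stages:
        o = cfg.oxidation
        report: dict[str, Any] = {}
        taus: dict[str, float | None] = {}
        for tag, fname in (("antioxidant", "oxidation_antioxidant.csv"),
                           ("control", "oxidation_control.csv")):
            curve = read_curve_csv(out / fname)
            try:
                res = ox.induction_time(curve, o.min_segment)
                report[tag] = res.to_dict()
                taus[tag] = res.tau_ind
            except (ox.NoBreakpointError, ox.InsufficientDataError) as exc:
                # a control without inhibitor shows no lag; record why
                report[tag] = {"tau_ind_h": None, "note": str(exc)}
                taus[tag] = None
        if taus["antioxidant"] and taus["control"]:
            report["effectiveness_ratio"] = taus["antioxidant"] / taus["control"]
        else:
            report["effectiveness_ratio"] = None
        _write_json(report, out / "induction_times.json")
        record("induction_times", out / "induction_times.json")
        stages_run.append("kinetics")

    manifest = {
        "seed": seed,
        "stages": stages_run,
        "config": cfg.model_dump(mode="json"),
        "outputs": {name: {"file": fname, "sha256": _sha256(out / fname)}
                    for name, fname in artifacts.items()},
    }
    _write_json(manifest, out / "manifest.json")
    return manifest
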