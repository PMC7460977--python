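"""End-to-end orchestration: structure → dimers → backend → J → λ → rates
→ diffusion/mobility → contacts, from one declarative config.

Reports are deterministic for a given config + seed (sorted keys, no
timestamps), and a provenance record echoes every physical default so the
output is self-describing.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import __version__
from .contacts import ContactTable, contact_fractions
from .crystal_model import (
    DEFAULT_DIMER_CUTOFF,
    CrystalStructure,
    DimerPair,
    dimer_table,
    enumerate_dimers,
    identify_molecules,
    read_cif,
)
from .errors import HopcrystalError, StageError, ValidationError
from .mobility import (
    DEFAULT_TEMPERATURE,
    HopSpec,
    MobilityReport,
    frontier_levels,
    hopping_diffusion,
    report_to_dict,
)
from .qc_backend import HuckelParams, huckel_dimer, huckel_monomer, load_external_matrices
from .reorganization import lambda_four_point
from .synthetic_data import StackSpec, make_acene_template, make_herringbone_crystal, make_stack_crystal
from .transfer_integral import TransferIntegral, dipro_coupling


@dataclass
class RunConfig:
    input_kind: str                        # cif | stack | herringbone
    input_path: str | None = None
    input_spec: dict = field(default_factory=dict)
    backend: str = "huckel"
    backend_params: dict = field(default_factory=dict)
    carriers: tuple = ("hole", "electron")
    temperature: float = DEFAULT_TEMPERATURE
    cutoff: float = DEFAULT_DIMER_CUTOFF
    convention: str = "msd"
    lambdas: dict = field(default_factory=dict)  # carrier → eV or {"adapter": path}
    delta_e_from_projection: bool = False
    output_dir: str | None = None
    seed: int = 0
    name: str = ""

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive")
        if self.input_kind == "cif":
            if not self.input_path or not os.path.exists(self.input_path):
                raise ValidationError(f"input CIF {self.input_path!r} does not exist")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        inp = raw.get("input", {})
        return cls(
            input_kind=inp.get("kind", "cif"),
            input_path=inp.get("path"),
            input_spec=inp.get("spec", {}),
            backend=raw.get("backend", "huckel"),
            backend_params=raw.get("backend_params", {}),
            carriers=tuple(raw.get("carriers", ["hole", "electron"])),
            temperature=float(raw.get("temperature", DEFAULT_TEMPERATURE)),
            cutoff=float(raw.get("cutoff", DEFAULT_DIMER_CUTOFF)),
            convention=raw.get("convention", "msd"),
            lambdas=raw.get("lambda", {}),
            output_dir=raw.get("output_dir"),
            seed=int(raw.get("seed", 0)),
            name=raw.get("name", ""),
        )


@dataclass
class PipelineResult:
    structure: CrystalStructure
    dimers: list[DimerPair]
    integrals: dict                       # carrier → list[TransferIntegral]
    lambdas: dict                         # carrier → eV
    reports: dict                         # carrier → MobilityReport
    contacts: ContactTable
    frontier: tuple | None = None         # (HOMO, LUMO, gap) eV


def _build_structure(config: RunConfig) -> CrystalStructure:
    if config.input_kind == "cif":
        return read_cif(config.input_path)
    spec = dict(config.input_spec)
    template = make_acene_template(int(spec.pop("n_rings", 3)))
    if config.input_kind == "stack":
        return make_stack_crystal(StackSpec(template=template, **spec))
    if config.input_kind == "herringbone":
        return make_herringbone_crystal(template, **spec)
    raise ValidationError(f"unknown input kind {config.input_kind!r}")


def _resolve_lambda(config: RunConfig, carrier: str) -> float:
    spec = config.lambdas.get(carrier)
    if spec is None:
        raise ValidationError(f"no reorganization energy configured for carrier {carrier!r}")
    if isinstance(spec, dict) and "adapter" in spec:
        four = load_external_matrices(spec["adapter"])
        return lambda_four_point(four, carrier).lambda_total
    return float(spec)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all stages; on failure raises StageError naming the stage."""

    def stage(label, fn):
        try:
            return fn()
        except HopcrystalError as exc:
            raise StageError(label, str(exc)) from exc

    structure = stage("structure", lambda: _build_structure(config))
    structure = stage("molecules", lambda: identify_molecules(structure))
    dimers = stage("dimers", lambda: enumerate_dimers(structure, cutoff=config.cutoff))

    if config.backend != "huckel":
        raise StageError("backend", f"pipeline backend {config.backend!r} not supported "
                         "(use the library API for adapter-driven dimers)")
    params = HuckelParams(**config.backend_params)

    monomers = stage(
        "backend", lambda: [huckel_monomer(mol, params) for mol in structure.molecules]
    )
    frontier = stage("frontier", lambda: frontier_levels(monomers[0]))

    integrals: dict[str, list[TransferIntegral]] = {c: [] for c in config.carriers}
    lambdas = {c: _resolve_lambda(config, c) for c in config.carriers}
    for pair in dimers:
        dm = stage("backend", lambda p=pair: huckel_dimer(p.mol_a, p.mol_b, params))
        res_b = stage("backend", lambda p=pair: huckel_monomer(p.mol_b, params))
        for carrier in config.carriers:
            ti = stage(
                "coupling",
                lambda c=carrier, d=dm, p=pair: dipro_coupling(
                    d, monomers[p.central_index], res_b, c
                ),
            )
            integrals[carrier].append(ti)

    reports = {}
    for carrier in config.carriers:
        per_central: list[MobilityReport] = []
        for ci in sorted({p.central_index for p in dimers}) or [0]:
            hops = []
            for pair, ti in zip(dimers, integrals[carrier]):
                if pair.central_index != ci:
                    continue
                delta_e = ti.delta_e if config.delta_e_from_projection else 0.0
                for r_vec in pair.equivalent_r_vecs:
                    hops.append(
                        HopSpec(
                            J=abs(ti.J_eff),
                            lambda_=lambdas[carrier],
                            r_vec=r_vec,
                            delta_E=delta_e,
                            T=config.temperature,
                        )
                    )
            per_central.append(
                stage("mobility", lambda h=hops, c=carrier: hopping_diffusion(
                    h, convention=config.convention, carrier=c))
            )
        # Multi-site crystals: uniform average of D over central sites.
        d_tensor = np.mean([r.D_tensor for r in per_central], axis=0)
        d_iso = float(np.mean([r.D_iso for r in per_central]))
        mu = float(np.mean([r.mu for r in per_central]))
        combined = MobilityReport(
            per_direction=[row for r in per_central for row in r.per_direction],
            D_tensor=d_tensor,
            D_iso=d_iso,
            mu=mu,
            carrier=carrier,
            temperature=config.temperature,
            convention=config.convention,
            warnings=[w for r in per_central for w in r.warnings],
        )
        reports[carrier] = combined

    contacts = stage("contacts", lambda: contact_fractions(structure))

    result = PipelineResult(
        structure=structure,
        dimers=dimers,
        integrals=integrals,
        lambdas=lambdas,
        reports=reports,
        contacts=contacts,
        frontier=frontier,
    )
    if config.output_dir:
        stage("artifacts", lambda: write_artifacts(config, result))
    return result


def write_artifacts(config: RunConfig, result: PipelineResult) -> None:
    out = config.output_dir
    os.makedirs(out, exist_ok=True)

    def dump(name, obj):
        with open(os.path.join(out, name), "w") as fh:
            json.dump(obj, fh, indent=2, sort_keys=True)
            fh.write("\n")

    dump("dimers.json", dimer_table(result.dimers))
    dump("lambda.json", {c: v for c, v in sorted(result.lambdas.items())})
    dump("contacts.json", result.contacts.to_dict())
    for carrier, report in sorted(result.reports.items()):
        dump(f"mobility_{carrier}.json", report_to_dict(report))

    with open(os.path.join(out, "j_table.csv"), "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=[
            "structure", "dimer", "r_angstrom", "carrier", "J_raw_meV", "s_ab",
            "e_a_meV", "e_b_meV", "J_eff_meV"])
        writer.writeheader()
        from .transfer_integral import coupling_table_rows

        for carrier in sorted(result.integrals):
            for pair, ti in zip(result.dimers, result.integrals[carrier]):
                for row in coupling_table_rows(
                    result.structure.name, pair.fingerprint_hash(), pair.r, [ti]
                ):
                    writer.writerow(row)

    with open(os.path.join(out, "contacts.csv"), "w", newline="") as fh:
        rows = result.contacts.long_rows(result.structure.name)
        writer = csv.DictWriter(fh, fieldnames=["structure", "pair", "count",
                                                "fraction", "class"])
        writer.writeheader()
        writer.writerows(rows)

    dump("provenance.json", {
        "package": "hopcrystal",
        "version": __version__,
        "seed": config.seed,
        "temperature_K": config.temperature,
        "cutoff_angstrom": config.cutoff,
        "convention": config.convention,
        "backend": config.backend,
        "backend_params": {k: v for k, v in sorted(config.backend_params.items())},
        "carriers": list(config.carriers),
        "lambda_eV": {c: v for c, v in sorted(result.lambdas.items())},
        "input_kind": config.input_kind,
        "name": config.name,
    })
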