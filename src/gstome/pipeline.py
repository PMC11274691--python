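"""Whole-family orchestration: run every structure through the site,
geometry, pathway and elastic-network analyses and aggregate per-residue
results onto MSA numbers.

The aggregated family profile reports, per alignment column: how many
structures have that column in their dimerization interface (N_DI), in
their cofactor binding site (N_GS), visited by at least one shortest
communication pathway (N_path), the mean and standard deviation of the
predicted thermal B-factor, and the amino-acid occurrence (number of
non-gap rows).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import anm, geometry, msa, pathways, sites
from .structure import StructureModel, read_structure

log = logging.getLogger("gstome")


class PipelineError(ValueError):
    pass


@dataclass
class RunConfig:
    """Every tunable of the analysis in one place."""

    contact_threshold: float = 4.0  # Å, heavy-atom contact criterion
    ligand_cluster_threshold: float = 2.0  # Å, ligand single-linkage threshold
    probe_radius: float = 1.4  # Å, solvent probe for SASA
    sasa_points: int = 960
    his_positive: bool = False  # count His as +1 in formal charges
    gamma: float = 1.0  # ANM stiffness scale
    temperature: float = 300.0  # K
    distance_weighted_paths: bool = False
    compute_interface_area: bool = False  # SASA-difference buried area (slow)
    average_monomers: bool = True  # pool homodimer chains per MSA column
    chain_pairs: dict[str, tuple[str, str]] = field(default_factory=dict)
    class_labels: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("contact_threshold", "ligand_cluster_threshold", "probe_radius"):
            if getattr(self, name) <= 0:
                raise PipelineError(f"{name} must be positive")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class StructureReport:
    name: str
    secondary_structure: str
    radius_of_gyration: float
    interface: sites.InterfaceResult | None
    binding_sites: list[sites.BindingSiteResult]
    gs_msa_numbers: set[int]
    pathway: pathways.PathwayResult | None
    pathway_msa_numbers: set[int]
    mean_path_length: int | None
    bfactors_msa: pd.Series  # per-MSA-number predicted B


@dataclass
class GstomeReport:
    config: RunConfig
    per_structure: dict[str, StructureReport]
    profile: pd.DataFrame  # per-MSA-number aggregate
    rmsd_matrix: pd.DataFrame
    identity_matrix: pd.DataFrame
    correlations: pd.Series  # per-structure rho vs family mean B profile
    class_correlations: pd.Series
    errors: dict[str, str]


def monomer_to_msa_profile(
    values_a: np.ndarray,
    values_b: np.ndarray | None,
    aln: msa.AlignedSequenceSet,
    row_id: str,
    average: bool = True,
) -> pd.Series:
    """Scatter per-residue values of a (homodimeric) structure onto MSA
    numbers.  The two monomer values per sequence position are averaged
    (or chain A alone is used when ``values_b`` is None); gap columns are
    absent from the result."""
    row = aln.row(row_id)
    ungapped = len(row.replace("-", ""))
    values_a = np.asarray(values_a, float)
    if len(values_a) != ungapped:
        raise PipelineError(
            f"{row_id}: chain has {len(values_a)} values but alignment row "
            f"ungapped length is {ungapped}"
        )
    if values_b is not None:
        values_b = np.asarray(values_b, float)
        if len(values_b) != ungapped:
            raise PipelineError(f"{row_id}: second chain length mismatch")
        merged = (values_a + values_b) / 2.0 if average else values_a
    else:
        merged = values_a
    numbers, vals = [], []
    pos = 0
    for col, aa in enumerate(row, start=1):
        if aa == "-":
            continue
        numbers.append(col)
        vals.append(merged[pos])
        pos += 1
    return pd.Series(vals, index=numbers, name=row_id)


def _residue_values_per_chain(
    model: StructureModel, profile: anm.BFactorProfile
) -> list[np.ndarray]:
    out = []
    for chain in model.chains:
        out.append(
            np.array([profile.residue_bfactors[res.key] for res in chain.residues])
        )
    return out


def _assign_clusters_to_chains(
    model: StructureModel, clusters: sites.LigandClusterSet
) -> dict[str, sites.LigandCluster]:
    """Each cluster is attached to the chain whose atoms lie closest to
    its centroid."""
    chain_coords = {
        ch.id: np.vstack([r.coords() for r in ch.residues]) for ch in model.chains
    }
    best: dict[str, tuple[float, sites.LigandCluster]] = {}
    for cluster in clusters.clusters:
        dists = {
            cid: float(np.min(np.linalg.norm(coords - cluster.centroid, axis=1)))
            for cid, coords in chain_coords.items()
        }
        cid = min(dists, key=dists.get)
        if cid not in best or dists[cid] < best[cid][0]:
            best[cid] = (dists[cid], cluster)
    return {cid: cl for cid, (_, cl) in best.items()}


def analyze_structure(
    model: StructureModel,
    aln: msa.AlignedSequenceSet,
    row_id: str,
    config: RunConfig | None = None,
) -> StructureReport:
    """Full single-structure analysis against one alignment row."""
    cfg = config or RunConfig()
    chain_a = model.chains[0]

    ss = geometry.chain_secondary_structure(chain_a)
    rg = geometry.radius_of_gyration(model)

    interface = None
    if len(model.chains) == 2:
        interface = sites.interface_residues(
            model, threshold=cfg.contact_threshold, aln=aln, row_id=row_id,
            his_positive=cfg.his_positive,
        )
        if cfg.compute_interface_area:
            interface.buried_area = sites.buried_interface_area(
                model, probe=cfg.probe_radius, n_points=cfg.sasa_points
            )

    binding_sites: list[sites.BindingSiteResult] = []
    gs_numbers: set[int] = set()
    pathway = None
    path_numbers: set[int] = set()
    mean_len: int | None = None
    if model.ligands:
        clusters = sites.cluster_ligands(model.ligands, cfg.ligand_cluster_threshold)
        for cluster in clusters.clusters:
            bs = sites.binding_site_residues(
                model, cluster, threshold=cfg.contact_threshold,
                aln=aln, row_id=row_id, his_positive=cfg.his_positive,
            )
            binding_sites.append(bs)
            gs_numbers |= bs.msa_numbers
        by_chain = _assign_clusters_to_chains(model, clusters)
        if len(model.chains) == 2:
            cid_a, cid_b = model.chains[0].id, model.chains[1].id
            if cid_a in by_chain and cid_b in by_chain:
                apo = sites.binding_site_residues(
                    model, by_chain[cid_b], threshold=cfg.contact_threshold
                )
                cmap = sites.residue_contact_map(model, cfg.contact_threshold)
                rgraph = pathways.build_residue_graph(
                    model, cmap, by_chain[cid_a], apo.residues,
                    threshold=cfg.contact_threshold,
                    distance_weighted=cfg.distance_weighted_paths,
                )
                pathway = pathways.shortest_paths(rgraph)
                mean_len = pathway.path_length
                for idx in pathway.visited_residues:
                    path_numbers |= sites.residues_to_msa_numbers(
                        model, [cmap.residues[idx]], aln, row_id
                    )

    bprof = anm.predict_bfactors(model, gamma=cfg.gamma, temperature=cfg.temperature)
    chain_vals = _residue_values_per_chain(model, bprof)
    bf_msa = monomer_to_msa_profile(
        chain_vals[0],
        chain_vals[1] if len(chain_vals) > 1 else None,
        aln, row_id, average=cfg.average_monomers,
    )

    return StructureReport(
        name=row_id,
        secondary_structure=ss,
        radius_of_gyration=rg,
        interface=interface,
        binding_sites=binding_sites,
        gs_msa_numbers=gs_numbers,
        pathway=pathway,
        pathway_msa_numbers=path_numbers,
        mean_path_length=mean_len,
        bfactors_msa=bf_msa,
    )


def profile_correlation(
    per_structure_b: dict[str, pd.Series], gstome_mean_b: pd.Series
) -> pd.Series:
    """Pearson ρ of each structure's B profile against the family mean,
    over their shared MSA numbers.  NaN marks undefined (zero-variance or
    too-short) cases."""
    out = {}
    for name, series in per_structure_b.items():
        common = series.index.intersection(gstome_mean_b.index)
        if len(common) < 3:
            out[name] = np.nan
            continue
        x = series.loc[common].to_numpy()
        y = gstome_mean_b.loc[common].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            out[name] = np.nan
            continue
        out[name] = float(np.corrcoef(x, y)[0, 1])
    return pd.Series(out, name="rho").sort_index()


def run_gstome(
    config: RunConfig,
    structures_dir: str | Path,
    alignment_file: str | Path,
) -> GstomeReport:
    """Analyze a directory of PDB structures against one alignment.

    Every file stem must match an alignment row id; unmatched ids raise.
    Failures inside one structure are collected, not fatal."""
    aln = msa.read_alignment(Path(alignment_file).read_text())
    paths = sorted(Path(structures_dir).glob("*.pdb"))
    if not paths:
        raise PipelineError(f"no .pdb files in {structures_dir}")
    unmatched = [p.stem for p in paths if p.stem not in aln.ids]
    if unmatched:
        raise PipelineError(f"structures without alignment rows: {unmatched}")

    per_structure: dict[str, StructureReport] = {}
    models: dict[str, StructureModel] = {}
    errors: dict[str, str] = {}
    for p in paths:
        t0 = time.perf_counter()
        name = p.stem
        try:
            model = read_structure(p)
            if name in config.chain_pairs:
                model = model.subset(list(config.chain_pairs[name]))
            models[name] = model
            per_structure[name] = analyze_structure(model, aln, name, config)
            log.info("analyzed %s in %.2fs", name, time.perf_counter() - t0)
        except Exception as exc:  # noqa: BLE001 — batch robustness by design
            errors[name] = f"{type(exc).__name__}: {exc}"
            log.warning("failed %s: %s", name, errors[name])

    names = sorted(per_structure)
    ncols = aln.ncols
    index = pd.RangeIndex(1, ncols + 1, name="msa_number")
    n_di = pd.Series(0, index=index)
    n_gs = pd.Series(0, index=index)
    n_path = pd.Series(0, index=index)
    for rep in per_structure.values():
        if rep.interface is not None:
            for c in rep.interface.msa_numbers:
                n_di[c] += 1
        for c in rep.gs_msa_numbers:
            n_gs[c] += 1
        for c in rep.pathway_msa_numbers:
            n_path[c] += 1
    bmat = pd.DataFrame(
        {name: per_structure[name].bfactors_msa for name in names}, index=index
    )
    occurrence = pd.Series(
        [sum(1 for rid in aln.ids if rid in names and aln.row(rid)[c] != "-")
         for c in range(ncols)],
        index=index,
    )
    profile = pd.DataFrame({
        "n_di": n_di,
        "n_gs": n_gs,
        "n_path": n_path,
        "b_mean": bmat.mean(axis=1),
        "b_sd": bmat.std(axis=1, ddof=0),
        "occurrence": occurrence,
    })

    rmsd = pd.DataFrame(np.nan, index=names, columns=names)
    for i, na in enumerate(names):
        rmsd.loc[na, na] = 0.0
        for nb in names[i + 1:]:
            try:
                val = geometry.rmsd_common_calpha(models[na], models[nb], aln, na, nb)
            except geometry.GeometryError:
                continue
            rmsd.loc[na, nb] = rmsd.loc[nb, na] = val

    identity = msa.identity_matrix(aln)

    bseries = {name: per_structure[name].bfactors_msa for name in names}
    correlations = profile_correlation(bseries, profile["b_mean"])
    labels = config.class_labels
    if labels:
        cls = pd.Series({n: labels.get(n, "unknown") for n in correlations.index})
        class_corr = correlations.groupby(cls).mean()
    else:
        class_corr = pd.Series(dtype=float)

    return GstomeReport(
        config=config,
        per_structure=per_structure,
        profile=profile,
        rmsd_matrix=rmsd,
        identity_matrix=identity,
        correlations=correlations,
        class_correlations=class_corr,
        errors=errors,
    )


def write_report(report: GstomeReport, out_dir: str | Path) -> None:
    """Emit the aggregate tables as TSV plus a JSON manifest (config hash,
    per-structure summaries, collected errors)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.profile.to_csv(out / "gstome_profile.tsv", sep="\t", float_format="%.6g")
    report.rmsd_matrix.to_csv(out / "rmsd_matrix.tsv", sep="\t", float_format="%.6g")
    report.identity_matrix.to_csv(out / "identity_matrix.tsv", sep="\t", float_format="%.6g")
    report.correlations.to_csv(out / "bfactor_correlations.tsv", sep="\t", float_format="%.6g")
    manifest = {
        "config_digest": report.config.digest(),
        "config": asdict(report.config),
        "structures": {
            name: {
                "radius_of_gyration": rep.radius_of_gyration,
                "n_di": rep.interface.n_di if rep.interface else None,
                "interface_charge": rep.interface.charge_a if rep.interface else None,
                "buried_area": rep.interface.buried_area if rep.interface else None,
                "n_gs": [bs.n_gs for bs in rep.binding_sites],
                "gs_charge": [bs.charge for bs in rep.binding_sites],
                "mean_path_length": rep.mean_path_length,
                "n_paths": rep.pathway.n_paths if rep.pathway else None,
                "secondary_structure": rep.secondary_structure,
            }
            for name, rep in sorted(report.per_structure.items())
        },
        "errors": report.errors,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
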