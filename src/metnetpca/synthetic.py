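"""Synthetic study generators.

Two generators make the whole pipeline testable without any external data:

* a cohort generator emulating a multigroup, multiblock clinical
  metabolomics design — five cohorts measured on four LC-MS blocks, with a
  dominant planted severity gradient and a smaller dialysis-specific axis —
  returning both the data-matrix network and the planted ground truth;
* a toy pathway-annotated metabolic network with hub side compounds,
  carbon-transfer flags and planted module labels;
* a QC injection-sequence generator with planted signal drift and planted
  unreliable features for the preprocessing filters.

Everything is reproducible from the design seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_network import DataMatrix, DataNetwork, build_data_network
from .metnet import CompoundGraph
from .preprocess import FeatureRun

__all__ = [
    "CohortDesign",
    "CohortTruth",
    "NetworkDesign",
    "ToyNetwork",
    "paper_design",
    "generate_cohort",
    "generate_toy_network",
    "generate_qc_run",
    "annotate_variables",
]


@dataclass
class CohortDesign:
    """Design of the synthetic multigroup/multiblock cohort.

    ``groups`` maps each cohort to (n individuals, list of row-class labels,
    one per timepoint).  ``blocks`` maps each analytical block to its
    variable count.  ``severity_levels`` give the planted disease-severity
    latent level per row-class; ``secondary_levels`` the dialysis-specific
    axis.  Effects enter as rank-1 mean shifts over the support variables.
    """

    groups: dict[str, tuple[int, list[str]]]
    blocks: dict[str, int]
    severity_levels: dict[str, float]
    secondary_levels: dict[str, float]
    severity_support_frac: float = 0.5
    severity_amp_mean: float = 1.0
    severity_amp_sd: float = 0.3
    secondary_support_frac: float = 0.15
    secondary_amp_mean: float = 1.5
    secondary_amp_sd: float = 0.3
    subject_jitter_sd: float = 0.25
    subject_effect_sd: float = 0.0  # shared per-subject offset across timepoints
    noise_sd: float = 1.0
    heavy_tails: bool = False  # Student-t (df=4) noise instead of Gaussian
    seed: int = 0
    var_names: dict[str, list[str]] | None = None

    def __post_init__(self) -> None:
        if any(n < 1 for n, _ in self.groups.values()):
            raise ValueError("all group sizes must be >= 1")
        if any(v < 1 for v in self.blocks.values()):
            raise ValueError("all block sizes must be >= 1")
        for g, (_, rcs) in self.groups.items():
            for rc in rcs:
                if rc not in self.severity_levels:
                    raise ValueError(f"no severity level for row_class {rc!r}")

    @property
    def row_classes(self) -> list[str]:
        return [rc for _, (_, rcs) in self.groups.items() for rc in rcs]

    @property
    def n_matrices(self) -> int:
        return len(self.row_classes) * len(self.blocks)

    @property
    def n_profiles(self) -> int:
        return sum(n * len(rcs) for n, rcs in self.groups.values())

    @property
    def n_variables(self) -> int:
        return sum(self.blocks.values())


@dataclass
class CohortTruth:
    """Planted ground truth of a generated cohort."""

    severity: dict[str, np.ndarray]   # row_class -> per-observation latent level
    secondary: dict[str, np.ndarray]
    severity_support: dict[str, tuple[np.ndarray, np.ndarray]]   # block -> (idx, amp)
    secondary_support: dict[str, tuple[np.ndarray, np.ndarray]]
    var_ids: dict[str, list[str]]

    def severity_concat(self, row_classes: list[str]) -> np.ndarray:
        return np.concatenate([self.severity[rc] for rc in row_classes])

    def secondary_concat(self, row_classes: list[str]) -> np.ndarray:
        return np.concatenate([self.secondary[rc] for rc in row_classes])

    def export(self, directory) -> None:
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows = []
        for rc in self.severity:
            for i, (sev, sec) in enumerate(zip(self.severity[rc], self.secondary[rc])):
                rows.append({"row_class": rc, "index": i, "severity": sev, "secondary": sec})
        pd.DataFrame(rows).to_csv(directory / "truth_covariates.tsv", sep="\t", index=False)
        rows = []
        for b, (idx, amp) in self.severity_support.items():
            for i, a in zip(idx, amp):
                rows.append({"block": b, "axis": "severity", "var_id": self.var_ids[b][i], "amplitude": a})
        for b, (idx, amp) in self.secondary_support.items():
            for i, a in zip(idx, amp):
                rows.append({"block": b, "axis": "secondary", "var_id": self.var_ids[b][i], "amplitude": a})
        pd.DataFrame(rows).to_csv(directory / "truth_supports.tsv", sep="\t", index=False)


def paper_design(seed: int = 42, **overrides) -> CohortDesign:
    """The emulated study design: 5 cohorts, 10 row-classes, 4 blocks.

    Cohorts: 56 healthy controls (CTRL), 69 intermediate-stage CKD patients
    (ICKD), 35 hemodialysis patients sampled pre/post session, 42 kidney
    graft recipients (before, 1 week, 1 month) and 24 living kidney donors
    (before, 1 week, 1 year) — 393 profiles in 40 matrices.  Blocks: RPLC+
    (88 variables), RPLC- (38), aHILIC+ (27), ZICpHILIC- (65); 218 in total.

    Planted severity orders the row-classes CTRL ≈ preDV < ICKD < preHD ≈
    preKG, with post-dialysis and post-graft classes pulled back toward the
    intermediate level and donors returning to baseline; the secondary
    (dialysis) axis loads on postHD only.
    """
    design = CohortDesign(
        groups={
            "CTRL": (56, ["CTRL"]),
            "ICKD": (69, ["ICKD"]),
            "HD": (35, ["preHD", "postHD"]),
            "KG": (42, ["preKG", "postKG1", "postKG2"]),
            "DV": (24, ["preDV", "postDV1", "postDV2"]),
        },
        blocks={"RPLC+": 88, "RPLC-": 38, "aHILIC+": 27, "ZICpHILIC-": 65},
        severity_levels={
            "CTRL": 0.0,
            "ICKD": 1.0,
            "preHD": 2.0,
            "postHD": 0.9,
            "preKG": 1.9,
            "postKG1": 1.1,
            "postKG2": 0.8,
            "preDV": 0.0,
            "postDV1": 0.2,
            "postDV2": 0.1,
        },
        secondary_levels={
            rc: (-1.0 if rc == "postHD" else 0.0)
            for rc in [
                "CTRL", "ICKD", "preHD", "postHD", "preKG",
                "postKG1", "postKG2", "preDV", "postDV1", "postDV2",
            ]
        },
        seed=seed,
    )
    return replace(design, **overrides) if overrides else design


def _default_var_ids(design: CohortDesign) -> dict[str, list[str]]:
    if design.var_names is not None:
        out = {}
        for b, n in design.blocks.items():
            names = design.var_names.get(b)
            if names is None or len(names) != n:
                raise ValueError(f"var_names for block {b!r} must list exactly {n} ids")
            out[b] = [str(x) for x in names]
        return out
    safe = {b: b.replace("+", "pos").replace("-", "neg") for b in design.blocks}
    return {b: [f"{safe[b]}_v{j:03d}" for j in range(n)] for b, n in design.blocks.items()}


def _supports(design: CohortDesign) -> tuple[dict, dict]:
    """Effect supports and amplitudes, a deterministic function of the design."""
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 101]))
    sev, sec = {}, {}
    for b, n in design.blocks.items():
        k = max(1, round(design.severity_support_frac * n))
        idx = np.sort(rng.choice(n, size=k, replace=False))
        amp = np.abs(rng.normal(design.severity_amp_mean, design.severity_amp_sd, size=k))
        sev[b] = (idx, amp)
        k2 = max(1, round(design.secondary_support_frac * n))
        idx2 = np.sort(rng.choice(n, size=k2, replace=False))
        amp2 = np.abs(rng.normal(design.secondary_amp_mean, design.secondary_amp_sd, size=k2))
        sec[b] = (idx2, amp2)
    return sev, sec


def generate_cohort(design: CohortDesign) -> tuple[DataNetwork, CohortTruth]:
    """Generate the data-matrix network with planted effects.

    Each matrix is  severity(g) x severity_loadings(b)^T  +
    secondary(g) x secondary_loadings(b)^T  +  independent noise, where the
    per-observation latent levels are the design's row-class levels plus
    subject jitter (shared across a cohort's timepoints when the subject
    random effect is enabled).
    """
    var_ids = _default_var_ids(design)
    for b, ids in var_ids.items():
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate var ids in block {b!r}")
    sev_support, sec_support = _supports(design)
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 202]))

    sev_load = {}
    sec_load = {}
    for b, n in design.blocks.items():
        v = np.zeros(n)
        idx, amp = sev_support[b]
        v[idx] = amp
        sev_load[b] = v
        w = np.zeros(n)
        idx2, amp2 = sec_support[b]
        w[idx2] = amp2
        sec_load[b] = w

    severity: dict[str, np.ndarray] = {}
    secondary: dict[str, np.ndarray] = {}
    obs_ids: dict[str, list[str]] = {}
    for gname, (n, rcs) in design.groups.items():
        shared = rng.normal(0, design.subject_jitter_sd, size=n)
        subject_offset = (
            rng.normal(0, design.subject_effect_sd, size=n)
            if design.subject_effect_sd > 0
            else np.zeros(n)
        )
        for rc in rcs:
            jitter = shared if len(rcs) > 1 else rng.normal(0, design.subject_jitter_sd, size=n)
            severity[rc] = design.severity_levels[rc] + jitter + subject_offset
            secondary[rc] = np.full(n, design.secondary_levels.get(rc, 0.0))
            obs_ids[rc] = [f"{rc}_s{i:03d}" for i in range(n)]

    matrices = []
    for rc in design.row_classes:
        for b, nv in design.blocks.items():
            n = len(obs_ids[rc])
            if design.heavy_tails:
                noise = rng.standard_t(4, size=(n, nv)) * design.noise_sd
            else:
                noise = rng.normal(0, design.noise_sd, size=(n, nv))
            vals = (
                np.outer(severity[rc], sev_load[b])
                + np.outer(secondary[rc], sec_load[b])
                + noise
            )
            matrices.append(DataMatrix(vals, obs_ids[rc], var_ids[b], rc, b))
    network = build_data_network(matrices)
    truth = CohortTruth(
        severity=severity,
        secondary=secondary,
        severity_support=sev_support,
        secondary_support=sec_support,
        var_ids=var_ids,
    )
    return network, truth


# ---------------------------------------------------------------------------
# toy metabolic network


@dataclass
class NetworkDesign:
    """Design of the toy pathway-annotated metabolic network."""

    n_pathways: int = 5
    pathway_size: int = 6
    wiring: str = "cycle"  # or "chain"
    n_bridges: int = 4
    n_side_compounds: int = 2
    side_degree: int = 8
    non_carbon_fraction: float = 0.1
    seed: int = 11

    def __post_init__(self) -> None:
        if min(self.n_pathways, self.pathway_size) < 1 or self.n_side_compounds < 0:
            raise ValueError("counts must be positive")
        if self.n_side_compounds and self.side_degree < self.pathway_size:
            raise ValueError("side-compound degree must be >= pathway size (hubs)")
        if self.wiring not in {"chain", "cycle"}:
            raise ValueError("wiring must be 'chain' or 'cycle'")


@dataclass
class ToyNetwork:
    graph: CompoundGraph
    labels: pd.Series          # planted module label per pathway metabolite
    declared_nodes: int
    declared_edges: int


def generate_toy_network(design: NetworkDesign) -> ToyNetwork:
    """Build the toy network: pathway chains/cycles of carbon-transfer edges,
    hub side compounds spanning pathways, sparse carbon bridges between
    consecutive pathways, and a fraction of extra non-carbon edges."""
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 303]))
    graph = CompoundGraph()
    labels = {}
    mets: list[list[str]] = []
    for p in range(design.n_pathways):
        pid = f"pathway{p}"
        graph.pathways[pid] = f"Pathway {p}"
        row = []
        for i in range(design.pathway_size):
            node = f"P{p}m{i}"
            graph.add_metabolite(node, name=node, pathways={pid})
            labels[node] = p
            row.append(node)
        mets.append(row)
        for i in range(design.pathway_size - 1):
            graph.add_reaction_edge(row[i], row[i + 1], f"R_P{p}_{i}", carbon_transfer=True)
        if design.wiring == "cycle" and design.pathway_size > 2:
            graph.add_reaction_edge(row[-1], row[0], f"R_P{p}_loop", carbon_transfer=True)
        # each pathway has a connector metabolite (m0) wired more densely
        # within its pathway; bridges run connector-to-connector, so the
        # connectors are local degree hubs exactly like the ubiquitous
        # inter-pathway compounds the squared-degree path weighting penalizes
        for c, i in enumerate(range(2, design.pathway_size - 1, 2)):
            graph.add_reaction_edge(row[0], row[i], f"R_P{p}_chord{c}", carbon_transfer=True)

    for k in range(design.n_bridges):
        p = k % max(1, design.n_pathways - 1)
        graph.add_reaction_edge(mets[p][0], mets[p + 1][0], f"R_bridge{k}", carbon_transfer=True)

    all_mets = [m for row in mets for m in row]
    for j in range(design.n_side_compounds):
        node = f"side{j}"
        graph.add_metabolite(node, name=node, side_compound=True)
        targets = rng.choice(len(all_mets), size=min(design.side_degree, len(all_mets)), replace=False)
        for t_i, t in enumerate(sorted(targets)):
            graph.add_reaction_edge(node, all_mets[t], f"R_side{j}_{t_i}", carbon_transfer=True)

    n_extra = round(design.non_carbon_fraction * graph.n_edges)
    added = 0
    attempts = 0
    while added < n_extra and attempts < 100 * max(1, n_extra):
        attempts += 1
        u, v = rng.choice(len(all_mets), size=2, replace=False)
        u, v = all_mets[u], all_mets[v]
        if graph.g.has_edge(u, v):
            continue
        graph.add_reaction_edge(u, v, f"R_nc{added}", carbon_transfer=False)
        added += 1

    return ToyNetwork(
        graph=graph,
        labels=pd.Series(labels, name="module"),
        declared_nodes=design.n_pathways * design.pathway_size + design.n_side_compounds,
        declared_edges=graph.n_edges,
    )


def annotate_variables(
    design: CohortDesign,
    toy: ToyNetwork,
    target_pathway: str | None = None,
    mapped_fraction: float = 0.61,
) -> pd.DataFrame:
    """Variable annotation table linking cohort variables to network metabolites.

    Severity-support variables are named after the metabolites of
    ``target_pathway`` (cycled; defaults to the first pathway), so markers
    of the dominant axis land inside one planted pathway.  A further share
    of the remaining variables is spread over the other metabolites until
    roughly ``mapped_fraction`` of all variables carry a network name; the
    rest stay unmappable.  Deterministic given the design seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 404]))
    var_ids = _default_var_ids(design)
    sev_support, _ = _supports(design)
    if target_pathway is None:
        target_pathway = sorted(toy.graph.pathways)[0]
    members = sorted(
        n for n, d in toy.graph.g.nodes(data=True) if target_pathway in d["pathways"]
    )
    if not members:
        raise ValueError(f"pathway {target_pathway!r} has no members")
    others = sorted(
        n for n, d in toy.graph.g.nodes(data=True)
        if not d["side_compound"] and target_pathway not in d["pathways"]
    )

    rows = []
    support_vars = {
        var_ids[b][i] for b in design.blocks for i in sev_support[b][0]
    }
    cycle = 0
    n_total = design.n_variables
    n_target_mapped = round(mapped_fraction * n_total)
    mapped_so_far = 0
    flat_vars = [v for b in design.blocks for v in var_ids[b]]
    non_support = [v for v in flat_vars if v not in support_vars]
    rng.shuffle(non_support)
    extra_mapped = set(non_support[: max(0, n_target_mapped - len(support_vars))])
    for v in flat_vars:
        if v in support_vars:
            name = members[cycle % len(members)]
            cycle += 1
            mapped_so_far += 1
        elif v in extra_mapped and others:
            name = others[int(rng.integers(len(others)))]
            mapped_so_far += 1
        else:
            name = f"unannotated_{v}"
        rows.append({"var_id": v, "name": name})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# QC injection sequences


def generate_qc_run(
    n_features: int = 20,
    n_batches: int = 1,
    samples_per_batch: int = 48,
    qc_period: int = 6,
    drift_fold: float = 1.0,
    batch_scale: tuple[float, ...] | None = None,
    n_bad_ratio: int = 0,
    n_bad_rsd: int = 0,
    dilution: float = 0.5,
    noise_rsd: float = 0.02,
    seed: int = 7,
) -> tuple[FeatureRun, dict]:
    """Generate an injection sequence with QCs/dQCs and planted artefacts.

    Every ``qc_period`` injections a QC and an adjacent dQC are injected.
    ``drift_fold`` applies a linear multiplicative drift across each batch
    (1.0 = no drift).  ``n_bad_ratio`` features get a dQC/QC ratio of ~0.9
    (outside the 0.2-0.8 window) and ``n_bad_rsd`` features get wildly
    unstable ratios; both should be caught by the ratio filter.  Returns the
    run and a truth dict with the planted feature classes.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 505]))
    features = [f"F{j:03d}" for j in range(n_features)]
    baseline = rng.uniform(500, 5000, size=n_features)
    bad_ratio = set(features[:n_bad_ratio])
    bad_rsd = set(features[n_bad_ratio : n_bad_ratio + n_bad_rsd])
    if batch_scale is None:
        batch_scale = tuple(1.0 for _ in range(n_batches))

    meta_rows = []
    intens_rows = []
    for batch in range(n_batches):
        n_inj = samples_per_batch
        for order in range(1, n_inj + 1):
            pos_in_cycle = (order - 1) % qc_period
            if pos_in_cycle == 0:
                role = "QC"
                sample_id = f"QC_b{batch}_{order}"
            elif pos_in_cycle == 1:
                role = "dQC"
                sample_id = f"dQC_b{batch}_{order}"
            else:
                role = "sample"
                sample_id = f"S_b{batch}_{order}"
            drift = 1.0 + (drift_fold - 1.0) * (order - 1) / max(1, n_inj - 1)
            row = np.empty(n_features)
            for j, f in enumerate(features):
                level = baseline[j]
                if role == "dQC":
                    if f in bad_ratio:
                        level *= 0.9
                    elif f in bad_rsd:
                        level *= dilution * rng.uniform(0.1, 3.0)
                    else:
                        level *= dilution
                noise = rng.normal(1.0, noise_rsd)
                row[j] = level * drift * batch_scale[batch] * max(noise, 0.01)
            meta_rows.append(
                {"sample_id": sample_id, "role": role, "batch": batch, "order": order}
            )
            intens_rows.append(row)
    run = FeatureRun(
        pd.DataFrame(meta_rows),
        pd.DataFrame(np.asarray(intens_rows), columns=features),
    )
    truth = {
        "good": [f for f in features if f not in bad_ratio | bad_rsd],
        "bad_ratio": sorted(bad_ratio),
        "bad_rsd": sorted(bad_rsd),
    }
    return run, truth
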