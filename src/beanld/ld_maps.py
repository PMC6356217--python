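"""Analysis deliverables: LD heatmap matrices, inter-chromosomal high-LD
pairs, and the end-to-end pipeline orchestrator.

The correctness surface of the maps is the exported matrices and tables,
not rendered images; plotting is left to the caller (the matrices are
plain symmetric arrays ready for any heatmap routine).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import decay_fit, ld_core, qc_impute, structure_kinship, synthetic_panel
from .errors import IncompleteInputError, ValidationError
from .genotype_io import (
    GenotypeMatrix,
    read_tsv,
    read_vcf,
    recompute_locus_stats,
    write_tsv,
)

DEFAULT_TIERS = (0.7, 0.8, 0.9)


@dataclass
class HeatmapMatrix:
    """Position-ordered symmetric pairwise LD matrix for one chromosome."""

    chrom: str
    positions: np.ndarray
    values: np.ndarray
    measure: str


def intra_heatmap(
    records: pd.DataFrame, chrom: str, measure: str
) -> HeatmapMatrix:
    """Assemble the symmetric intra-chromosomal matrix for one measure.

    ``records`` must cover every within-chromosome pair of the chromosome
    (as produced by :func:`beanld.ld_core.pairwise_ld`); the diagonal is 1.
    """
    if measure not in ld_core.LD_MEASURES:
        raise ValidationError(f"unknown measure {measure!r}")
    sel = records[
        (records["chrom_a"] == chrom) & (records["chrom_b"] == chrom)
    ]
    positions = np.unique(
        np.concatenate([sel["pos_a"].to_numpy(), sel["pos_b"].to_numpy()])
    )
    index = {p: i for i, p in enumerate(positions)}
    k = len(positions)
    mat = np.full((k, k), np.nan)
    np.fill_diagonal(mat, 1.0)
    for row in sel.itertuples(index=False):
        i = index[row.pos_a]
        j = index[row.pos_b]
        val = getattr(row, measure)
        mat[i, j] = val
        mat[j, i] = val
    off = ~np.eye(k, dtype=bool)
    if np.isnan(mat[off]).any() and k > 1:
        i, j = np.argwhere(np.isnan(mat) & off)[0]
        raise IncompleteInputError(
            f"missing pair {chrom}:{positions[i]} x {chrom}:{positions[j]}"
        )
    return HeatmapMatrix(
        chrom=chrom, positions=positions, values=mat, measure=measure
    )


def interchrom_pairs(
    records: pd.DataFrame,
    tiers: tuple[float, ...] = DEFAULT_TIERS,
    *,
    measure: str = "rvs2",
) -> pd.DataFrame:
    """Cross-chromosome pairs at or above the lowest tier, tier-annotated.

    The tier of a pair is the greatest threshold not exceeding its value;
    output is sorted by value descending (position-lexicographic on ties).
    """
    tiers = tuple(sorted(tiers))
    if not tiers:
        raise ValidationError("at least one tier required")
    sel = records[~records["same_chrom"].astype(bool)].copy()
    sel = sel[sel[measure] >= tiers[0]]
    tier_vals = np.full(len(sel), tiers[0])
    for t in tiers:
        tier_vals[sel[measure].to_numpy() >= t] = t
    sel["tier"] = tier_vals
    sel = sel.sort_values(
        [measure, "chrom_a", "pos_a", "chrom_b", "pos_b"],
        ascending=[False, True, True, True, True],
    ).reset_index(drop=True)
    return sel


def tier_counts(pairs: pd.DataFrame, tiers=DEFAULT_TIERS, *, measure="rvs2") -> dict:
    """Cumulative pair counts at each threshold (>= t)."""
    return {
        str(t): int((pairs[measure] >= t).sum()) for t in sorted(tiers)
    }


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "max_missing": 0.10,
    "min_maf": 0.05,
    "window": "auto",
    "window_range": [5, 150],
    "k_pcs": 4,
    "tw_alpha": 0.05,
    "fdr": 0.05,
    "scope": "all_pairs",
    "decay_threshold": 0.1,
    "decay_measures": ["r2", "rs2", "rv2", "rvs2"],
    "interchrom_tiers": [0.7, 0.8, 0.9],
    "interchrom_measure": "rvs2",
}


def _load_input(config: dict):
    if "simulate" in config:
        spec = synthetic_panel.spec_from_dict(config["simulate"])
        G, L, truth = synthetic_panel.simulate_panel(spec)
        return G, L, truth
    path = config.get("input")
    if path is None:
        raise ValidationError("config needs either 'simulate' or 'input'")
    if str(path).endswith((".vcf", ".vcf.gz")):
        G, L = read_vcf(path)
    else:
        G, L = read_tsv(path)
    return G, L, None


def run_pipeline(config: dict, outdir: str | Path | None = None) -> dict:
    """Execute qc -> impute -> structure -> kinship -> ld -> decay -> maps.

    ``config`` is a declarative dict (see :data:`DEFAULT_CONFIG` for the
    thresholds and their defaults; a ``simulate`` sub-dict or an ``input``
    path selects the data source). Returns a machine-readable summary;
    when ``outdir`` is given, intermediates and the summary are persisted
    there. Fully deterministic given the config.
    """
    cfg = {**DEFAULT_CONFIG, **config}
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    G_raw, L_raw, truth = _load_input(cfg)
    wlo, whi = cfg["window_range"]
    G, L, report = qc_impute.run_qc(
        G_raw,
        L_raw,
        max_md=cfg["max_missing"],
        min_maf=cfg["min_maf"],
        window=cfg["window"],
        window_candidates=range(int(wlo), int(whi) + 1),
    )
    L = recompute_locus_stats(G, L)

    pca = structure_kinship.pca_scores(G)
    tw_count = structure_kinship.tracy_widom_count(
        pca.eigenvalues, G.n_accessions, G.n_loci, alpha=cfg["tw_alpha"]
    )
    k_pcs = tw_count if cfg["k_pcs"] == "auto" else int(cfg["k_pcs"])
    k_pcs = min(k_pcs, pca.scores.shape[1])
    S = structure_kinship.build_S(pca, k=k_pcs)
    kin = structure_kinship.kinship_sm(G)

    records = ld_core.pairwise_ld(
        G,
        L,
        S,
        kin,
        scope=cfg["scope"],
        fdr_q=cfg["fdr"],
    )

    within = records[records["same_chrom"].astype(bool)]
    decay_summary: dict[str, dict] = {}
    for meas in cfg["decay_measures"]:
        sub = within.dropna(subset=[meas])
        if len(sub) < 10:
            continue
        fit = decay_fit.fit_C(
            sub["distance_bp"].to_numpy(),
            sub[meas].to_numpy(),
            G.n_accessions,
            measure=meas,
        )
        dist = decay_fit.decay_distance(fit, cfg["decay_threshold"])
        decay_summary[meas] = {
            "rho_per_bp": fit.rho_per_bp,
            "sse": fit.sse,
            "n_pairs": fit.n_pairs,
            "at_lower_bound": fit.at_lower_bound,
            "at_upper_bound": fit.at_upper_bound,
            "decay_distance_bp": dist,
        }

    inter = interchrom_pairs(
        records,
        tuple(cfg["interchrom_tiers"]),
        measure=cfg["interchrom_measure"],
    )
    inter_counts = tier_counts(
        inter, cfg["interchrom_tiers"], measure=cfg["interchrom_measure"]
    )

    summary = {
        "n_accessions": G.n_accessions,
        "qc": report.to_dict(),
        "n_loci_final": G.n_loci,
        "loci_per_chrom": {
            str(c): int((L["chrom"] == c).sum()) for c in L["chrom"].unique()
        },
        "k_pcs": k_pcs,
        "tracy_widom_count": tw_count,
        "pc_variance_fraction": [
            float(f) for f in pca.variance_fraction[: max(k_pcs, 4)]
        ],
        "kinship_smin": kin.smin,
        "n_ld_records": int(len(records)),
        "n_fdr_significant": int(records["fdr_significant"].sum()),
        "decay": decay_summary,
        "interchrom_pair_counts": inter_counts,
    }
    if truth is not None:
        pools = sorted(set(truth.pool_label) - {synthetic_panel.RIL_LABEL})
        pi_by_pool = {}
        for pool in pools:
            idx = [i for i, p in enumerate(truth.pool_label) if p == pool]
            if len(idx) >= 2:
                pi_by_pool[pool] = structure_kinship.nucleotide_diversity(G, idx)
        pi_by_pool["all"] = structure_kinship.nucleotide_diversity(G)
        summary["nucleotide_diversity"] = pi_by_pool

    if outdir is not None:
        write_tsv(G, L, outdir / "genotypes.filtered.tsv")
        np.savetxt(outdir / "structure_S.tsv", S.S, delimiter="\t")
        pd.DataFrame(
            kin.V, index=G.accession_ids, columns=G.accession_ids
        ).to_csv(outdir / "kinship_V.tsv", sep="\t")
        records.to_csv(outdir / "ld_records.tsv", sep="\t", index=False)
        inter.to_csv(outdir / "interchrom_pairs.tsv", sep="\t", index=False)
        (outdir / "summary.json").write_text(
            json.dumps(summary, sort_keys=True, indent=2) + "\n"
        )
    return summary
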