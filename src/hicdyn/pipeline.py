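"""End-to-end orchestration of the analysis stages on one dataset.

The pipeline ties the stages together through their public interfaces only:
simulation (or file input) -> balancing -> compartment calling -> switch
classification -> TADs -> trans statistics -> FISH.  Every stochastic step is
seeded from one root seed, so a rerun with the same configuration produces
bit-identical outputs; ``run`` writes a manifest with SHA-256 checksums of
every emitted file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import compartments, contacts, simulate, tads, trans

logger = logging.getLogger("hicdyn")


def balance_and_pc1(
    raw_maps: dict,
    orientation: np.ndarray,
    ice_tol: float = 1e-5,
    mask_quantile: float = 0.02,
) -> tuple[dict, dict]:
    """ICE-balance every raw map and compute its PC1 compartment track.

    Returns ``(balanced_oe_maps, tracks)`` keyed like ``raw_maps``; the O/E
    maps are reused by saddle/decay statistics.
    """
    oe_maps, tracks = {}, {}
    for key, cmap in raw_maps.items():
        bal = contacts.ice_balance(cmap, tol=ice_tol, mask_quantile=mask_quantile)
        oe = contacts.oe_normalize(bal)
        oe_maps[key] = oe
        tracks[key] = compartments.compute_pc1(oe, orientation, sample="_".join(key))
    return oe_maps, tracks


def switch_recovery(config: simulate.HiCSimConfig, alpha: float = 0.05) -> dict:
    """Simulate a time course and recover the planted compartment dynamics.

    The orientation track is the gene density from the generated annotation.
    Returns the switch calls, the planted truth, and recovered-vs-true summary
    numbers (switching fraction and per-category shares).
    """
    raw_maps, truth = simulate.gen_hic(config)
    track_data = simulate.gen_tracks(config, truth)
    oe_maps, tracks = balance_and_pc1(raw_maps, track_data["gene_density"])
    timepoints = [f"t{t}" for t in range(config.n_timepoints)]
    calls = compartments.classify_switches(tracks, timepoints, alpha=alpha)
    switching = ~calls["category"].isin(compartments.STABLE_CATEGORIES)
    called_fraction = float(switching.mean())
    shares = {}
    n_sw = int(switching.sum())
    for cat in compartments.SWITCH_CATEGORIES:
        shares[cat] = float((calls["category"] == cat).sum() / n_sw) if n_sw else 0.0
    return {
        "calls": calls,
        "tracks": tracks,
        "raw_maps": raw_maps,
        "oe_maps": oe_maps,
        "truth": truth,
        "track_data": track_data,
        "called_switching_fraction": called_fraction,
        "true_switching_fraction": truth.switching_fraction,
        "called_category_shares": shares,
        "true_category_shares": truth.category_shares(),
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run(config: dict, outdir: str | Path) -> dict:
    """Run the demo pipeline on generated data and write a checksum manifest.

    ``config`` mirrors :class:`~hicdyn.simulate.HiCSimConfig` fields plus
    ``alpha`` (switch test), ``n_permutations`` (trans test), and FISH
    parameters.  Outputs: per-sample matrices and PC1 bedGraphs, switch calls
    (BED), saddle grid (TSV), boundary sets (BED), trans permutation summary
    (JSON), FISH distances (CSV), ground truth (JSON) and ``manifest.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_keys = {
        k: v for k, v in config.items() if k in simulate.HiCSimConfig.__dataclass_fields__
    }
    sim = simulate.HiCSimConfig(**sim_keys)
    alpha = config.get("alpha", 0.05)
    n_perm = config.get("n_permutations", 1000)
    seed = sim.seed

    logger.info("simulating time course: %s", sim)
    result = switch_recovery(sim, alpha=alpha)
    raw_maps, truth = result["raw_maps"], result["truth"]
    files: list[Path] = []

    bins_path = outdir / "bins.bed"
    next(iter(raw_maps.values())).bins.write_bed(bins_path)
    files.append(bins_path)
    for (tp, rep), cmap in raw_maps.items():
        p = outdir / f"matrix_{tp}_{rep}.txt"
        cmap.write(p)
        files.append(p)
    for key, track in result["tracks"].items():
        p = outdir / f"pc1_{'_'.join(key)}.bedgraph"
        df = track.to_frame()
        contacts.write_bedgraph(df, p, value_col="score")
        files.append(p)

    calls = result["calls"]
    p = outdir / "switch_calls.bed"
    calls_out = calls[["chrom", "start", "end", "category", "anova_p"]]
    calls_out.to_csv(p, sep="\t", header=False, index=False, float_format="%.6g")
    files.append(p)

    # saddle on the last time point, first replicate
    oe_maps = result["oe_maps"]
    last = (f"t{sim.n_timepoints - 1}", "r1")
    sad = compartments.saddle(oe_maps[last], result["tracks"][last])
    p = outdir / "saddle_last.tsv"
    np.savetxt(p, sad.grid, delimiter="\t", fmt="%.6g")
    files.append(p)

    tad_map, tad_truth = simulate.gen_tad_hic(seed=seed + 11)
    bal40 = contacts.ice_balance(tad_map)
    ins = tads.insulation_score(bal40)
    bnd = tads.insulation_boundaries(ins)
    p = outdir / "boundaries_insulation.bed"
    bnd.to_csv(p, sep="\t", header=False, index=False)
    files.append(p)

    if sim.n_hub_genes > 0:
        genes = result["track_data"]["genes"]
        hub = genes[genes["gene_id"].isin(truth.hub_genes)]
        # pooled late map
        late_keys = [k for k in raw_maps if k[0] == f"t{sim.n_timepoints - 1}"]
        pooled = raw_maps[late_keys[0]].matrix.copy()
        for k in late_keys[1:]:
            pooled = pooled + raw_maps[k].matrix
        pooled_map = contacts.ice_balance(
            contacts.ContactMap(raw_maps[late_keys[0]].bins, pooled)
        )
        perm = trans.permutation_null(pooled_map, hub, genes, n=n_perm, seed=seed + 17)
        p = outdir / "trans_permutation.json"
        with open(p, "w") as fh:
            json.dump(
                {"observed": perm["observed"], "p": perm["p"], "n": n_perm},
                fh,
                indent=1,
            )
        files.append(p)

    from . import fish as fish_mod

    spot_table, spot_truth = simulate.gen_spots(
        n_cells=config.get("fish_n_cells", 200),
        p_true=config.get("fish_p_true", 0.4),
        seed=seed + 23,
    )
    p = outdir / "spots.csv"
    spot_table.to_csv(p, index=False)
    files.append(p)
    ref_volume = float(spot_table.groupby("cell_id")["nucleus_volume"].first().mean())
    dist = fish_mod.cell_distances(spot_table, ref_volume)
    p = outdir / "fish_distances.csv"
    dist.to_csv(p, index=False)
    files.append(p)

    p = outdir / "ground_truth.json"
    truth.to_json(p)
    files.append(p)

    manifest = {
        "config": {**sim_keys, "alpha": alpha, "n_permutations": n_perm},
        "files": {f.name: _sha256(f) for f in files},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
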