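"""End-to-end annotation: extract -> admit -> map -> score -> cluster -> rank.

Given a directory of neighbor structures and one alignment file per
query-neighbor pair, :func:`run_annotate` produces a ranked list of inferred
binding-site clusters on the query, together with TSV/JSON reports.  When
the query has a structure of its own, its observed sites enter the pool
alongside the inferred ones (via an identity self-alignment); a bare-
sequence query is served by the alignments alone.

Reports are byte-stable: deterministic ordering everywhere and fixed float
formatting (6 significant digits).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .align import (MappedSite, PairwiseAlignment, admit_neighbor,
                    compose_through_query, identity_self_alignment,
                    load_alignment, map_site_to_query)
from .cluster import (ClusteringResult, complete_linkage,
                      distance_from_similarity, select_cutoff)
from .config import RunConfig
from .errors import DegenerateSiteError
from .evaluate import jackknife_filter
from .ligands import LigandPolicy, is_nonbiological, load_nonbio_codes
from .matrix import load_matrix
from .ranking import (ClusterScore, RankedAnnotation, SiteAlignment,
                      avg_identity_to_query, avg_interfacial_contacts,
                      build_pssm, conservation_entropy, henikoff_weights,
                      is_singleton, pssm_score_query, rank_clusters)
from .scoring import (ScoringParams, bit_score, conservation_score_cs,
                      raw_site_score, self_raw_score)
from .structure import extract_binding_sites, read_structure

log = logging.getLogger("homolig")

GAP = "-"


@dataclass
class AnnotationResult:
    query_id: str
    annotation: RankedAnnotation | None
    mapped_sites: list[MappedSite]
    clustering: ClusteringResult | None
    status: str
    counts: dict = field(default_factory=dict)


def _ligand_policy(config: RunConfig) -> LigandPolicy:
    codes = load_nonbio_codes(config.nonbio_list)
    return LigandPolicy(min_heavy_atoms=config.min_heavy_atoms,
                        mw_range=(config.mw_low, config.mw_high),
                        exclude_ions=config.exclude_ions,
                        nonbio_codes=codes)


def _scoring_params(config: RunConfig) -> ScoringParams:
    return ScoringParams(matrix=load_matrix(config.matrix_path),
                         theta=config.theta, gap_penalty=config.gap_penalty,
                         lambda_=config.lambda_, K=config.K, span=config.span)


def load_alignments(alignment_dir, query_id: str) -> list[PairwiseAlignment]:
    paths = sorted(Path(alignment_dir).glob("*.tsv")) + \
        sorted(Path(alignment_dir).glob("*.fasta"))
    alignments = []
    for path in paths:
        aln = load_alignment(path)
        if aln.query_id == query_id:
            alignments.append(aln)
    return alignments


def _query_sequence(alignments: list[PairwiseAlignment]) -> dict[int, str]:
    seq: dict[int, str] = {}
    for aln in alignments:
        for p in aln.pairs:
            seq.setdefault(p.q_res, p.q_aa)
    return seq


def _cluster_scores(clusters: list[list[int]], mapped: list[MappedSite],
                    alignments: dict[str, PairwiseAlignment],
                    query_seq: dict[int, str], policy: LigandPolicy,
                    config: RunConfig, matrix) -> list[ClusterScore]:
    scores = []
    all_q_positions = sorted({p.q_res for aln in alignments.values()
                              for p in aln.pairs})
    for ci, members in enumerate(clusters):
        sites = [mapped[i] for i in members]
        member_ids = [s.neighbor_id for s in sites]
        ligand_codes = [s.site.ligand.ligand_code for s in sites]
        columns = sorted({p for s in sites for p in s.query_positions})
        rows = []
        full_rows = []
        for s in sites:
            q2n = alignments[s.neighbor_id].query_to_neighbor()
            rows.append("".join(q2n[p].n_aa if p in q2n else GAP
                                for p in columns))
            full_rows.append("".join(q2n[p].n_aa if p in q2n else GAP
                                     for p in all_q_positions))
        aln_obj = SiteAlignment(columns, member_ids, rows, full_rows)
        weights = henikoff_weights(full_rows)
        score = ClusterScore(
            cluster_id=f"C{ci+1}",
            member_ids=member_ids,
            ligand_codes=ligand_codes,
            query_positions=columns,
        )
        score.nonbiological = all(is_nonbiological(c, policy)
                                  for c in ligand_codes)
        score.singleton = is_singleton(full_rows, config.redundancy_cutoff)
        if not score.singleton:
            score.conservation = conservation_entropy(aln_obj, weights)
            pssm = build_pssm(aln_obj, weights, matrix)
            query_residues = [query_seq.get(p, GAP) for p in columns]
            score.pssm_score = pssm_score_query(pssm, query_residues,
                                                config.pssm_gap_mode)
            score.avg_contacts = avg_interfacial_contacts(
                [s.site.total_contacts for s in sites])
            score.avg_identity = avg_identity_to_query(
                [alignments[s.neighbor_id].percent_identity for s in sites])
        scores.append(score)
    return scores


def run_annotate(config: RunConfig) -> AnnotationResult:
    """Run the full annotation pipeline for one query."""
    policy = _ligand_policy(config)
    params = _scoring_params(config)
    counts: dict[str, int] = {}

    if config.alignment_dir is None:
        raise ValueError("alignment_dir is required")
    alignments = load_alignments(config.alignment_dir, config.query_id)
    counts["alignments_loaded"] = len(alignments)

    admitted = [a for a in alignments
                if admit_neighbor(a, config.min_identity)]
    log.info("admitted %d/%d neighbors at >=%.0f%% identity",
             len(admitted), len(alignments), 100 * config.min_identity)
    if config.jackknife_ceiling is not None:
        admitted = jackknife_filter(admitted, config.query_id,
                                    config.jackknife_ceiling)
        log.info("jackknife ceiling %.2f leaves %d neighbors",
                 config.jackknife_ceiling, len(admitted))
    counts["neighbors_admitted"] = len(admitted)

    aln_by_id = {a.neighbor_id: a for a in admitted}
    mapped: list[MappedSite] = []

    # observed sites on the query structure itself
    if config.query_structure:
        qc = read_structure(config.query_structure)
        chain = qc.chains[0]
        self_aln = identity_self_alignment(config.query_id, chain.sequence,
                                           chain.residue_numbers())
        aln_by_id[config.query_id] = self_aln
        for site in extract_binding_sites(
                qc, policy, config.contact_cutoff,
                config.min_site_residues, config.chain_majority):
            ms = map_site_to_query(site, self_aln, config.min_footprint,
                                   config.footprint_mode)
            if ms is not None:
                mapped.append(ms)

    n_sites = n_rejected = 0
    for aln in admitted:
        if aln.neighbor_id == config.query_id:
            continue
        spath = None
        for ext in (".pdb", ".cif", ".ent"):
            candidate = Path(config.structure_dir) / f"{aln.neighbor_id}{ext}"
            if candidate.exists():
                spath = candidate
                break
        if spath is None:
            log.warning("no structure file for neighbor %s", aln.neighbor_id)
            continue
        cx = read_structure(spath)
        sites = extract_binding_sites(cx, policy, config.contact_cutoff,
                                      config.min_site_residues,
                                      config.chain_majority)
        n_sites += len(sites)
        for site in sites:
            ms = map_site_to_query(site, aln, config.min_footprint,
                                   config.footprint_mode)
            if ms is None:
                n_rejected += 1
            else:
                mapped.append(ms)
    counts["observed_sites"] = n_sites
    counts["footprint_rejected"] = n_rejected
    counts["mapped_sites"] = len(mapped)
    log.info("%d sites mapped into the query frame (%d rejected by the "
             "footprint rule)", len(mapped), n_rejected)

    if not mapped:
        result = AnnotationResult(config.query_id, None, [], None,
                                  "no sites could be inferred "
                                  "(no admitted neighbors or no transferable sites)",
                                  counts)
        if config.out_dir:
            write_reports(result, config)
        return result

    n = len(mapped)
    sim_cs = np.eye(n)
    sim_bits = np.zeros((n, n))
    for i in range(n):
        site_i = {r: aa for r, aa in mapped[i].site.residues}
        sim_bits[i, i] = bit_score(self_raw_score(site_i, params), params)
    for i in range(n):
        for j in range(i + 1, n):
            composed = compose_through_query(aln_by_id[mapped[i].neighbor_id],
                                             aln_by_id[mapped[j].neighbor_id])
            site_a = {r: aa for r, aa in mapped[i].site.residues}
            site_b = {r: aa for r, aa in mapped[j].site.residues}
            try:
                pair = conservation_score_cs(site_a, site_b, composed, params)
                cs, bits = pair.cs, pair.bits
            except DegenerateSiteError:
                cs = 0.0
                bits = bit_score(raw_site_score(site_a, site_b, composed,
                                                params), params)
            sim_cs[i, j] = sim_cs[j, i] = cs
            sim_bits[i, j] = sim_bits[j, i] = bits

    # cluster on CS distance; the free-energy cutoff weighs bit scores,
    # which go negative for unrelated sites
    dist = distance_from_similarity(sim_cs)
    dendrogram = complete_linkage(dist)
    clustering = select_cutoff(dendrogram, sim_bits, config.temperature)
    counts["clusters"] = len(clustering.clusters)

    query_seq = _query_sequence(list(aln_by_id.values()))
    scores = _cluster_scores(clustering.clusters, mapped, aln_by_id,
                             query_seq, policy, config, params.matrix)
    annotation = rank_clusters(scores, config.weights, config.query_id)
    counts["ranked_clusters"] = len(annotation.ranked)
    counts["excluded_nonbiological"] = len(annotation.excluded)

    result = AnnotationResult(config.query_id, annotation, mapped,
                              clustering, "ok", counts)
    if config.out_dir:
        write_reports(result, config)
    return result


def _fmt(x) -> str:
    return format(x, ".6g")


def report_rows(result: AnnotationResult) -> list[dict]:
    rows = []
    if result.annotation is None:
        return rows
    for s in result.annotation.ranked + result.annotation.excluded:
        rows.append({
            "rank": s.rank if s.rank is not None else "",
            "cluster_id": s.cluster_id,
            "combined": _fmt(s.combined) if s.combined is not None else "",
            "z_conservation": _fmt(s.z[0]) if s.z else "",
            "z_pssm": _fmt(s.z[1]) if s.z else "",
            "z_contacts": _fmt(s.z[2]) if s.z else "",
            "z_identity": _fmt(s.z[3]) if s.z else "",
            "conservation": _fmt(s.conservation),
            "pssm_score": _fmt(s.pssm_score),
            "avg_contacts": _fmt(s.avg_contacts),
            "avg_identity": _fmt(s.avg_identity),
            "n_members": len(s.member_ids),
            "members": ",".join(s.member_ids),
            "ligands": ",".join(sorted(set(s.ligand_codes))),
            "site_residues": ",".join(str(p) for p in s.query_positions),
            "singleton": int(s.singleton),
            "nonbiological": int(s.nonbiological),
        })
    return rows


def write_reports(result: AnnotationResult, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = report_rows(result)
    header = ["rank", "cluster_id", "combined", "z_conservation", "z_pssm",
              "z_contacts", "z_identity", "conservation", "pssm_score",
              "avg_contacts", "avg_identity", "n_members", "members",
              "ligands", "site_residues", "singleton", "nonbiological"]
    with open(out / "report.tsv", "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[h]) for h in header) + "\n")
    payload = {
        "query_id": result.query_id,
        "status": result.status,
        "counts": result.counts,
        "clusters": rows,
    }
    (out / "report.json").write_text(json.dumps(payload, indent=2,
                                                sort_keys=True))
    if result.clustering is not None:
        (out / "clustering.json").write_text(result.clustering.to_json())
    config.to_yaml(out / "run_config.yaml")
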