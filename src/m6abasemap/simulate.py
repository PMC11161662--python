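"""Self-contained synthetic data for the whole pipeline.

Generates a toy genome + annotation, true per-site m6A fractions under
configurable deposition models, binomial mutation pileups with spike-in
calibration probes, replicated tissues with shared/specific sites,
diverged ortholog pairs and phenotype tables — everything the analysis
stages consume, with the ground truth serialized for recovery tests.

What it emulates (and what it does not): multi-exon transcript models with
plant-like exon lengths; 3'UTR-enriched deposition and an optional
stop-codon-proximal deposition peak; ~0.5% mutation background on
unmodified A with motif-specific full-conversion rates; negative-binomial
depth variation; sample-to-sample conversion-efficiency jitter read out by
the spike-ins.  It does not model read-level errors, UMI structure, indel
evolution in orthologs or isoform diversity.

Random-number discipline: a master seed spawns named child streams
(genome, truth, pileup, orthologs, phenotypes), so adding draws to one
stage never perturbs the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import Region, TranscriptModel, assign_region, write_fasta, write_gff3

__all__ = [
    "SimConfig",
    "child_rng",
    "simulate_genome",
    "simulate_truth",
    "simulate_calibration_truth",
    "simulate_pileup",
    "simulate_orthologs",
    "simulate_phenotypes",
    "simulate_peaks",
    "write_simulation",
]

_STREAMS = {"genome": 0, "truth": 1, "pileup": 2, "orthologs": 3, "phenotypes": 4, "peaks": 5}


def child_rng(seed: int, stream: str) -> np.random.Generator:
    """Named child stream of the master seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


@dataclass
class SimConfig:
    """Study-condition knobs for the generator.

    Defaults emulate the plant setting: short internal exons (log-normal,
    median ~150 nt), a longer last exon carrying a 100-400 nt 3'UTR,
    sequencing depth ~NB(mean 100, dispersion 0.3), per-motif background
    mutation rates around 0.5% with full-conversion rates in [0.7, 0.95],
    detection-relevant deposition odds strongly favoring the 3'UTR, and
    two replicates per tissue.
    """

    seed: int = 0
    n_genes: int = 50
    exon_count_range: tuple[int, int] = (2, 8)
    exon_length_meanlog: float = 5.0
    exon_length_sdlog: float = 0.6
    exon_length_min: int = 30
    last_exon_meanlog: float = 6.2
    last_exon_sdlog: float = 0.4
    intron_length_range: tuple[int, int] = (60, 300)
    utr5_range: tuple[int, int] = (20, 150)
    utr3_range: tuple[int, int] = (100, 400)
    intergenic_gap: int = 200
    depth_mean: float = 100.0
    depth_dispersion: float = 0.3
    background_range: tuple[float, float] = (0.002, 0.01)
    full_rate_range: tuple[float, float] = (0.7, 0.95)
    conversion_jitter: float = 0.05
    spikein_fractions: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    spikein_depth: int = 2000
    deposition: dict = field(
        default_factory=lambda: {"model": "region_weighted", "p": {"5UTR": 0.01, "CDS": 0.02, "3UTR": 0.10}}
    )
    fraction_beta: tuple[float, float] = (2.0, 2.0)
    n_tissues: int = 4
    n_replicates: int = 2
    tissue_shared_prob: float = 0.5
    tissue_member_prob: float = 0.5
    n_ortholog_pairs: int = 50
    ortholog_length: int = 300
    substitution_rate: float = 0.1
    phenotype_alpha: float = 1.0
    phenotype_beta: float = 0.5
    phenotype_sigma: float = 0.3

    def validate(self) -> None:
        if self.exon_length_min < 1:
            raise ValueError("exon length minimum must be >= 1")
        lo, hi = self.exon_count_range
        if not 1 <= lo <= hi:
            raise ValueError("infeasible exon count range")
        if not 0 <= self.substitution_rate < 1:
            raise ValueError("substitution rate must be in [0, 1)")
        for r in (self.background_range, self.full_rate_range):
            if not 0 <= r[0] <= r[1] <= 1:
                raise ValueError(f"rate range {r} outside [0, 1]")


# ---------------------------------------------------------------------------
# Genome + annotation
# ---------------------------------------------------------------------------


def simulate_genome(cfg: SimConfig) -> tuple[dict[str, str], dict[str, TranscriptModel]]:
    """Deterministic toy genome: non-overlapping genes on one chromosome.

    Returns (chrom -> sequence, transcript_id -> model); models carry the
    spliced sense-strand sequence.
    """
    cfg.validate()
    rng = child_rng(cfg.seed, "genome")
    models: dict[str, TranscriptModel] = {}
    cursor = cfg.intergenic_gap
    placed: list[tuple[list[tuple[int, int]], str]] = []
    for gi in range(cfg.n_genes):
        n_exons = int(rng.integers(cfg.exon_count_range[0], cfg.exon_count_range[1] + 1))
        lengths = np.maximum(
            cfg.exon_length_min,
            rng.lognormal(cfg.exon_length_meanlog, cfg.exon_length_sdlog, size=n_exons).astype(int),
        )
        strand = "+" if gi % 2 == 0 else "-"
        # the transcript-3' exon carries the 3'UTR: make it longer
        last_len = max(
            cfg.utr3_range[1] + 60,
            int(rng.lognormal(cfg.last_exon_meanlog, cfg.last_exon_sdlog)),
        )
        if strand == "+":
            lengths[-1] = last_len
        else:
            lengths[0] = last_len  # leftmost genomic exon is transcript-3' on minus strand
        introns = rng.integers(cfg.intron_length_range[0], cfg.intron_length_range[1] + 1, size=max(0, n_exons - 1))
        exons = []
        pos = cursor
        for k, L in enumerate(lengths):
            exons.append((pos, pos + int(L)))
            pos += int(L)
            if k < n_exons - 1:
                pos += int(introns[k])
        cursor = pos + cfg.intergenic_gap
        placed.append((exons, strand))

    genome_len = cursor + cfg.intergenic_gap
    seq = rng.choice(list("ACGT"), size=genome_len, p=[0.3, 0.2, 0.2, 0.3])
    chrom_seq = "".join(seq)
    sequences = {"chr1": chrom_seq}

    from .annotation import reverse_complement

    for gi, (exons, strand) in enumerate(placed):
        gene_id = f"g{gi:04d}"
        tid = f"{gene_id}.t1"
        ordered = exons if strand == "+" else exons[::-1]
        tx_seq = "".join(chrom_seq[s:e] for s, e in sorted(exons))
        if strand == "-":
            tx_seq = reverse_complement(tx_seq)
        total = len(tx_seq)
        first_len = ordered[0][1] - ordered[0][0]
        last_len = ordered[-1][1] - ordered[-1][0]
        utr5 = int(rng.integers(cfg.utr5_range[0], min(cfg.utr5_range[1], max(cfg.utr5_range[0] + 1, first_len - 10)) + 1))
        utr3 = int(rng.integers(cfg.utr3_range[0], min(cfg.utr3_range[1], last_len - 30) + 1))
        cds_start = min(utr5, total // 4)
        cds_end = total - utr3
        if cds_end - cds_start < 30:
            cds_start, cds_end = max(0, total // 10), max(total // 2, 33)
        cds_end -= (cds_end - cds_start) % 3  # whole codons
        models[tid] = TranscriptModel(
            tid, gene_id, "chr1", strand, list(ordered), cds_start, cds_end, tx_seq
        )
    return sequences, models


# ---------------------------------------------------------------------------
# Truth: deposition models
# ---------------------------------------------------------------------------


def _deposition_prob(cfg_dep: dict, region: Region, offset: int, t: TranscriptModel) -> float:
    model = cfg_dep.get("model", "uniform")
    if model == "uniform":
        return float(cfg_dep.get("p", 0.02))
    if model == "region_weighted":
        return float(cfg_dep["p"].get(region.value, 0.0))
    if model == "stop_peak":
        base = float(cfg_dep.get("baseline", 0.005))
        amp = float(cfg_dep.get("amplitude", 0.05))
        mu = float(cfg_dep.get("mu", 300.0))
        sigma = float(cfg_dep.get("sigma", 75.0))
        anchor = cfg_dep.get("anchor", "last_junction")
        if anchor == "stop_codon":
            if not t.is_coding:
                return base
            d = offset - t.cds_end
        else:  # distance into the transcript-last exon from its 5' start
            ts, te = t.exon_transcript_intervals()[-1]
            if not ts <= offset < te:
                return base
            d = offset - ts
        p = base + amp * float(np.exp(-((d - mu) ** 2) / (2.0 * sigma**2)))
        if p > 1.0:
            raise ValueError("deposition amplitude yields probability > 1")
        return p
    raise ValueError(f"unknown deposition model {model!r}")


def simulate_truth(
    models: dict[str, TranscriptModel],
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw true m6A sites on candidate A positions.

    Every exonic A with a full NNANN context is a candidate; a Bernoulli
    indicator with position-dependent probability (per the deposition
    model) decides sitehood, and fractions come from a Beta distribution.
    Returns all candidates with ``is_site`` and ``true_fraction`` (0 for
    non-sites) plus genomic coordinates, region and motif — the truth set
    serialized next to the generated pileups.
    """
    rng = child_rng(cfg.seed, "truth") if rng is None else rng
    rows = []
    a, b = cfg.fraction_beta
    for tid in sorted(models):
        t = models[tid]
        seq = t.sequence
        if seq is None:
            raise ValueError(f"{tid}: transcript sequence required")
        for off in range(2, len(seq) - 2):
            if seq[off] != "A":
                continue
            gpos = t.transcript_to_genomic(off)
            region = assign_region(gpos, t)
            p = _deposition_prob(cfg.deposition, region, off, t)
            is_site = bool(rng.random() < p)
            frac = float(rng.beta(a, b)) if is_site else 0.0
            rows.append(
                {
                    "chrom": t.chrom,
                    "pos": gpos + 1,
                    "strand": t.strand,
                    "transcript_id": tid,
                    "offset": off,
                    "region": region.value,
                    "motif": seq[off - 2 : off + 3],
                    "is_site": is_site,
                    "true_fraction": frac,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pileups + spike-ins
# ---------------------------------------------------------------------------


def simulate_calibration_truth(motifs: list[str], cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-motif true background / full-conversion mutation rates."""
    motifs = sorted(set(motifs))
    return pd.DataFrame(
        {
            "motif": motifs,
            "bg_rate": rng.uniform(*cfg.background_range, size=len(motifs)),
            "full_rate": rng.uniform(*cfg.full_rate_range, size=len(motifs)),
        }
    )


def _nb_depth(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    if dispersion <= 0:
        return np.full(size, int(round(mean)))
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size)


def simulate_pileup(
    truth: pd.DataFrame,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[tuple[str, int], pd.DataFrame], dict[tuple[str, int], pd.DataFrame], pd.DataFrame, pd.DataFrame]:
    """Binomial pileups per tissue x replicate, plus matched spike-ins.

    Returns (pileups, spikeins, calibration_truth, tissue_membership);
    keys are (tissue_id, replicate).  mut_count ~ Binomial(depth,
    bg + f_eff * (full - bg) * sample_scale) where f_eff is the site's true
    fraction when the site is deposited in that tissue, else 0.  Every
    candidate A row is emitted, modified or not.
    """
    rng = child_rng(cfg.seed, "pileup") if rng is None else rng
    cal_truth = simulate_calibration_truth(list(truth["motif"]), cfg, rng)
    bg = dict(zip(cal_truth["motif"], cal_truth["bg_rate"]))
    full = dict(zip(cal_truth["motif"], cal_truth["full_rate"]))

    tissues = [f"tissue{k + 1}" for k in range(cfg.n_tissues)]
    site_idx = truth.index[truth["is_site"]]
    member = pd.DataFrame(False, index=truth.index, columns=tissues)
    for i in site_idx:
        if rng.random() < cfg.tissue_shared_prob:
            member.loc[i, :] = True
        else:
            picks = rng.random(cfg.n_tissues) < cfg.tissue_member_prob
            if not picks.any():
                picks[rng.integers(cfg.n_tissues)] = True
            member.loc[i, :] = picks

    bg_arr = truth["motif"].map(bg).to_numpy(dtype=float)
    full_arr = truth["motif"].map(full).to_numpy(dtype=float)
    frac_arr = truth["true_fraction"].to_numpy(dtype=float)

    pileups: dict[tuple[str, int], pd.DataFrame] = {}
    spikeins: dict[tuple[str, int], pd.DataFrame] = {}
    for tissue in tissues:
        present = member[tissue].to_numpy()
        for rep in range(1, cfg.n_replicates + 1):
            scale = 1.0 + rng.uniform(-cfg.conversion_jitter, cfg.conversion_jitter)
            full_s = np.clip(full_arr * scale, 0.0, 1.0)
            rate = bg_arr + np.where(present, frac_arr, 0.0) * (full_s - bg_arr)
            depth = _nb_depth(rng, cfg.depth_mean, cfg.depth_dispersion, len(truth))
            mut = rng.binomial(depth, rate)
            pileups[(tissue, rep)] = pd.DataFrame(
                {
                    "chrom": truth["chrom"].to_numpy(),
                    "pos": truth["pos"].to_numpy(),
                    "strand": truth["strand"].to_numpy(),
                    "depth": depth,
                    "mut_count": mut,
                    "motif": truth["motif"].to_numpy(),
                }
            )
            sp_rows = []
            for motif in cal_truth["motif"]:
                f_full = min(1.0, full[motif] * scale)
                for kf in cfg.spikein_fractions:
                    d = cfg.spikein_depth
                    r = bg[motif] + kf * (f_full - bg[motif])
                    sp_rows.append(
                        {
                            "motif": motif,
                            "known_fraction": kf,
                            "depth": d,
                            "mut_count": int(rng.binomial(d, r)),
                        }
                    )
            spikeins[(tissue, rep)] = pd.DataFrame(sp_rows)
    return pileups, spikeins, cal_truth, member


# ---------------------------------------------------------------------------
# Orthologs
# ---------------------------------------------------------------------------


def simulate_orthologs(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, dict[str, tuple[str, str]], dict[str, list[int]]]:
    """Ancestor sequences mutated independently per species (no indels).

    Returns (ortholog table, pair_id -> (seq_a, seq_b), pair_id -> true
    conserved A positions).  Truth: positions where both descendants kept
    an A with gap-free identical +/-1 flanks — exactly the rule the
    conservation stage must recover.
    """
    rng = child_rng(cfg.seed, "orthologs") if rng is None else rng
    cfg.validate()
    bases = np.array(list("ACGT"))
    table_rows, seqs, truths = [], {}, {}
    for k in range(cfg.n_ortholog_pairs):
        anc = rng.choice(bases, size=cfg.ortholog_length, p=[0.3, 0.2, 0.2, 0.3])

        def mutate(ancestor: np.ndarray) -> np.ndarray:
            out = ancestor.copy()
            hit = rng.random(len(out)) < cfg.substitution_rate
            for i in np.flatnonzero(hit):
                out[i] = rng.choice(bases[bases != out[i]])
            return out

        sa, sb = mutate(anc), mutate(anc)
        a_str, b_str = "".join(sa), "".join(sb)
        conserved = [
            i
            for i in range(1, len(a_str) - 1)
            if a_str[i] == "A"
            and b_str[i] == "A"
            and a_str[i - 1] == b_str[i - 1]
            and a_str[i + 1] == b_str[i + 1]
        ]
        pid = f"pair{k:03d}"
        table_rows.append({"gene_a": f"osA{k:03d}", "gene_b": f"atB{k:03d}", "pair_id": pid})
        seqs[pid] = (a_str, b_str)
        truths[pid] = conserved
    return pd.DataFrame(table_rows), seqs, truths


# ---------------------------------------------------------------------------
# Phenotypes + peaks
# ---------------------------------------------------------------------------


def simulate_phenotypes(
    fraction_sum_3utr: pd.Series,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Phenotypes depending on 3'UTR m6A burden.

    log-value = alpha + beta * fraction_sum_3utr + Normal(0, sigma); the
    exported ``value`` is exp(log_value) (e.g. lifetime in hours).
    """
    if cfg.phenotype_sigma <= 0:
        raise ValueError("phenotype sigma must be > 0")
    rng = child_rng(cfg.seed, "phenotypes") if rng is None else rng
    x = fraction_sum_3utr.to_numpy(dtype=float)
    logv = cfg.phenotype_alpha + cfg.phenotype_beta * x + rng.normal(0.0, cfg.phenotype_sigma, len(x))
    return pd.DataFrame(
        {
            "transcript_id": fraction_sum_3utr.index,
            "log_value": logv,
            "value": np.exp(logv),
        }
    )


def simulate_peaks(
    truth: pd.DataFrame, rng: np.random.Generator | None = None, seed: int = 0, jitter: int = 30, width: int = 100
) -> pd.DataFrame:
    """BED-like reader peaks centered near true 3'UTR sites (jittered)."""
    rng = child_rng(seed, "peaks") if rng is None else rng
    sel = truth.loc[truth["is_site"] & (truth["region"] == "3UTR")]
    centers = sel["pos"].to_numpy() - 1 + rng.integers(-jitter, jitter + 1, size=len(sel))
    return pd.DataFrame(
        {
            "chrom": sel["chrom"].to_numpy(),
            "start": np.maximum(0, centers - width // 2),
            "end": centers + width // 2,
            "name": [f"peak{i}" for i in range(len(sel))],
            "score": 0,
            "strand": sel["strand"].to_numpy(),
        }
    )


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------


def write_simulation(cfg: SimConfig, outdir: str | Path) -> dict[str, object]:
    """Run the full generator and emit every downstream input format.

    Writes genome.fa, annotation.gff3, pileup_<tissue>_rep<k>.tsv,
    spikein_<tissue>_rep<k>.tsv, orthologs.tsv (+ ortholog_seqs.fa),
    phenotypes.tsv, peaks.bed and truth.json.  Byte-identical for an
    identical config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sequences, models = simulate_genome(cfg)
    truth = simulate_truth(models, cfg)
    pileups, spikeins, cal_truth, member = simulate_pileup(truth, cfg)
    ortho_table, ortho_seqs, ortho_truth = simulate_orthologs(cfg)

    fs3 = truth.loc[truth["is_site"] & (truth["region"] == "3UTR")].groupby("transcript_id")[
        "true_fraction"
    ].sum()
    fs3 = fs3.reindex(sorted(models), fill_value=0.0)
    phen = simulate_phenotypes(fs3, cfg)
    peaks = simulate_peaks(truth, seed=cfg.seed)

    write_fasta(sequences, outdir / "genome.fa")
    write_gff3(models, outdir / "annotation.gff3")
    for (tissue, rep), df in pileups.items():
        df.to_csv(outdir / f"pileup_{tissue}_rep{rep}.tsv", sep="\t", index=False)
    for (tissue, rep), df in spikeins.items():
        df.to_csv(outdir / f"spikein_{tissue}_rep{rep}.tsv", sep="\t", index=False)
    ortho_table.to_csv(outdir / "orthologs.tsv", sep="\t", index=False)
    write_fasta(
        {f"{pid}_a": s[0] for pid, s in ortho_seqs.items()} | {f"{pid}_b": s[1] for pid, s in ortho_seqs.items()},
        outdir / "ortholog_seqs.fa",
    )
    phen.to_csv(outdir / "phenotypes.tsv", sep="\t", index=False)
    peaks.to_csv(outdir / "peaks.bed", sep="\t", index=False, header=False)
    truth.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(
            {
                "config": asdict(cfg),
                "calibration": cal_truth.to_dict(orient="list"),
                "ortholog_conserved": ortho_truth,
                "tissue_membership": {
                    str(i): row for i, row in zip(member.index.tolist(), member.to_numpy().tolist())
                },
            },
            fh,
            indent=0,
            sort_keys=True,
        )
    return {
        "sequences": sequences,
        "models": models,
        "truth": truth,
        "pileups": pileups,
        "spikeins": spikeins,
        "calibration_truth": cal_truth,
        "membership": member,
        "orthologs": (ortho_table, ortho_seqs, ortho_truth),
        "phenotypes": phen,
        "peaks": peaks,
    }
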