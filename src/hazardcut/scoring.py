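"""Per-sample biomarker scoring from an expression matrix.

Three scorer families cover the 12 markers: single-gene TPM values
(EGFR, CD44, SLC3A2), rank-based gene-set scores for the multi-gene
signatures (hypoxia, proliferation, immune, EMT, DNA crosslink repair),
and set-ratio scores contrasting two signatures (CD8+ vs Treg).

The set scorer is a rank-z mean: within each sample, genes are converted
to average ranks, the ranks standardized to mean 0 / sd 1, and the score
is the mean standardized rank over the signature's genes (minus the mean
over the down set, when present).  Like GSVA/ssGSEA it depends only on
the within-sample gene ordering, so any strictly monotone per-sample
transformation of the expression values (counts vs TPM, log or not)
leaves the scores bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger("hazardcut")


@dataclass(frozen=True)
class GeneSignature:
    """A named gene set with an associated scoring mode."""

    name: str
    genes_up: tuple[str, ...]
    genes_down: tuple[str, ...] = ()
    scoring: str = "rank_set"  # single_gene | rank_set | set_ratio
    partner: str | None = None  # denominator signature for set_ratio
    description: str = ""

    def __post_init__(self):
        if not self.genes_up:
            raise ValueError(f"signature {self.name!r}: genes_up must be non-empty")
        overlap = set(self.genes_up) & set(self.genes_down)
        if overlap:
            raise ValueError(f"signature {self.name!r}: genes in both up and down sets: {sorted(overlap)}")
        if self.scoring not in ("single_gene", "rank_set", "set_ratio"):
            raise ValueError(f"unknown scoring mode {self.scoring!r}")


def read_gmt(path) -> list[GeneSignature]:
    """Parse a GMT file: one signature per line (name, description, genes).

    Duplicate gene symbols within a set are removed with a warning.
    """
    sigs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT parse error at line {lineno}: expected >=3 tab-separated fields")
            name, desc, genes = fields[0], fields[1], fields[2:]
            genes = [g for g in genes if g]
            seen, uniq = set(), []
            for g in genes:
                if g in seen:
                    logger.warning("GMT %s line %d: duplicate gene %r removed", name, lineno, g)
                else:
                    seen.add(g)
                    uniq.append(g)
            sigs.append(GeneSignature(name=name, genes_up=tuple(uniq), description=desc))
    return sigs


# ---------------------------------------------------------------------------
# Normalization and scorers
# ---------------------------------------------------------------------------


def counts_to_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million from raw counts and effective gene lengths.

    Per sample: rate_g = count_g / length_g; TPM_g = rate_g / sum(rate) * 1e6,
    so every sample column sums to one million.
    """
    lengths = pd.Series(lengths)
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise ValueError(f"genes without length: {sorted(missing)[:10]}")
    L = lengths.loc[counts.index].to_numpy(dtype=float)
    if (L <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = counts.to_numpy(dtype=float) / L[:, None]
    total = rate.sum(axis=0)
    zero = total == 0
    if zero.any():
        raise ValueError(f"all-zero samples: {list(counts.columns[zero])}")
    tpm = rate / total[None, :] * 1e6
    return pd.DataFrame(tpm, index=counts.index, columns=counts.columns)


def score_single_gene(tpm: pd.DataFrame, gene: str, log2: bool = False) -> pd.Series:
    """A single gene's TPM row as a per-sample score; optional log2(x+1)."""
    if gene not in tpm.index:
        raise KeyError(f"gene {gene!r} not in expression matrix")
    score = tpm.loc[gene].astype(float)
    if log2:
        score = np.log2(score + 1)
    return pd.Series(score, index=tpm.columns, name=gene)


def _present_genes(expr: pd.DataFrame, sig_name: str, genes) -> list[str]:
    present = [g for g in genes if g in expr.index]
    missing = [g for g in genes if g not in expr.index]
    if missing:
        if len(missing) >= 0.5 * len(genes):
            raise ValueError(
                f"signature {sig_name!r}: {len(missing)}/{len(genes)} genes missing from matrix"
            )
        logger.warning("signature %s: dropping %d missing genes: %s", sig_name, len(missing), missing)
    return present


def score_rank_set(expr: pd.DataFrame, sig: GeneSignature) -> pd.Series:
    """Rank-z mean set score per sample.

    Genes are rank-transformed within each sample (average ranks on ties),
    ranks standardized to mean 0 / sd 1, and the score is the mean over the
    up set minus the mean over the down set.
    """
    up = _present_genes(expr, sig.name, sig.genes_up)
    down = _present_genes(expr, sig.name, sig.genes_down) if sig.genes_down else []
    X = expr.to_numpy(dtype=float)
    ranks = rankdata(X, axis=0)  # average ranks within each sample column
    mean = ranks.mean(axis=0, keepdims=True)
    sd = ranks.std(axis=0, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0  # all-tied sample: every standardized rank is 0
    z = (ranks - mean) / sd
    zdf = pd.DataFrame(z, index=expr.index, columns=expr.columns)
    score = zdf.loc[up].mean(axis=0)
    if down:
        score = score - zdf.loc[down].mean(axis=0)
    score.name = sig.name
    return score


def score_set_ratio(score_a: pd.Series, score_b: pd.Series, quotient: bool = False) -> pd.Series:
    """Contrast of two set scores (A relative to B).

    The default is the difference of the standardized set scores, which is
    well-defined for scores centered at zero; ``quotient=True`` computes a
    literal ratio and requires strictly positive inputs.
    """
    if not score_a.index.equals(score_b.index):
        raise ValueError("sample mismatch between score vectors")
    if quotient:
        if (score_a <= 0).any() or (score_b <= 0).any():
            raise ValueError("quotient ratio requires strictly positive scores")
        return score_a / score_b
    return score_a - score_b


def score_matrix(
    expr: pd.DataFrame,
    signatures: list[GeneSignature],
    tpm: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Compute the full samples x markers score matrix.

    ``expr`` feeds the rank-based scorers (counts or TPM — immaterial under
    rank transformation); ``tpm`` feeds single-gene scores and defaults to
    ``expr``.  ``set_ratio`` signatures reference their denominator partner
    by name and are computed after all set scores.
    """
    if tpm is None:
        tpm = expr
    by_name = {s.name: s for s in signatures}
    scores: dict[str, pd.Series] = {}
    provenance: dict[str, str] = {}
    for sig in signatures:
        if sig.scoring == "single_gene":
            gene = sig.genes_up[0]
            scores[sig.name] = score_single_gene(tpm, gene)
            provenance[sig.name] = "TPM"
        elif sig.scoring == "rank_set":
            scores[sig.name] = score_rank_set(expr, sig)
            provenance[sig.name] = "rank-z set score"
    for sig in signatures:
        if sig.scoring == "set_ratio":
            if sig.partner is None or sig.partner not in by_name:
                raise ValueError(f"set_ratio signature {sig.name!r} needs a valid partner")
            numer = score_rank_set(expr, sig)
            denom = scores.get(sig.partner)
            if denom is None:
                denom = score_rank_set(expr, by_name[sig.partner])
            scores[sig.name] = score_set_ratio(numer, denom)
            provenance[sig.name] = f"rank-z score contrast vs {sig.partner}"
    out = pd.DataFrame({s.name: scores[s.name] for s in signatures})
    out.attrs["provenance"] = {s.name: provenance.get(s.name, "") for s in signatures}
    return out


def read_expression(path) -> pd.DataFrame:
    """Tab-separated expression matrix: first column gene id, header = samples."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_scores(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, sep="\t", index_label="sample")
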