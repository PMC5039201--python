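"""Synthetic pooled-competition data generator.

Emulates a genome-wide yeast knock-out (YKO) Bar-seq experiment: a barcoded
strain library competing in continuous culture under basal or osmotic-stress
media, sampled by amplicon sequencing of the strain barcodes. Every
downstream stage (counting, filtering, fitness testing, clustering,
enrichment) can therefore be exercised against known ground truth.

Fitness is parameterised by per-strain selection coefficients ``s`` in log2
units per generation, so after ``G`` generations of exponential competition
a strain's expected log2 fold-change versus a neutral pool is ``G * s``.

Randomness: each public function takes one integer ``seed`` and draws from a
single ``numpy.random.default_rng(seed)`` stream, in the order documented in
its docstring, so identical inputs give identical outputs.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    BASE_BYTES,
    CONDITIONS,
    DEFAULT_LAYOUT,
    ReadLayout,
    codes_to_seq,
    seq_to_codes,
)

TAG_LENGTH = 20
MIN_TAG_DISTANCE = 5  # guarantees unambiguous assignment at <=2 mismatches
INDEX_LENGTH = 6
MIN_INDEX_DISTANCE = 3


# ---------------------------------------------------------------------------
# strain library

def _pairwise_min_distance_conflicts(codes: np.ndarray, min_distance: int,
                                     block: int = 1024) -> np.ndarray:
    """Row indices i that sit closer than min_distance to some row j < i."""
    n, L = codes.shape
    onehot = (codes[:, :, None] == np.arange(4)).reshape(n, 4 * L).astype(np.float32)
    bad = np.zeros(n, dtype=bool)
    for start in range(0, n, block):
        stop = min(start + block, n)
        sim = onehot[start:stop] @ onehot.T  # shared positions
        dist = L - sim
        for i in range(start, stop):
            row = dist[i - start, :i]
            if row.size and row.min() < min_distance:
                bad[i] = True
    return np.nonzero(bad)[0]


def generate_catalog(n_strains: int, seed: int = 0, *,
                     collection: str = "homozygous",
                     genes: list[str] | None = None,
                     min_distance: int = MIN_TAG_DISTANCE,
                     max_rounds: int = 50) -> pd.DataFrame:
    """Generate a tag catalog: per strain one 20-mer up-tag and one down-tag.

    All 2*n tags (up and down pooled) are pairwise Hamming distance
    ``min_distance`` apart, which makes <=2-mismatch tag assignment
    unambiguous. Tags are drawn uniformly and conflicting rows redrawn;
    random 20-mers essentially never collide at distance 5, so redraw rounds
    are rare, but a hard ``max_rounds`` cap turns pathological requests into
    an error instead of an endless loop.

    Returns a DataFrame with columns strain_id, gene, up_tag, down_tag,
    collection. Draw order: one (2n, 20) uniform base matrix, then redraws.
    """
    if n_strains < 1:
        raise ValueError("n_strains must be >= 1")
    if collection not in ("homozygous", "heterozygous"):
        raise ValueError(f"unknown collection {collection!r}")
    rng = np.random.default_rng(seed)
    n_tags = 2 * n_strains
    codes = rng.integers(0, 4, size=(n_tags, TAG_LENGTH), dtype=np.uint8)
    for _ in range(max_rounds):
        bad = _pairwise_min_distance_conflicts(codes, min_distance)
        if bad.size == 0:
            break
        codes[bad] = rng.integers(0, 4, size=(bad.size, TAG_LENGTH), dtype=np.uint8)
    else:
        raise RuntimeError(
            f"could not draw {n_tags} tags at pairwise distance >= {min_distance} "
            f"in {max_rounds} rounds"
        )
    if genes is None:
        genes = [f"GENE{i + 1:04d}" for i in range(n_strains)]
    elif len(genes) != n_strains:
        raise ValueError("genes list length must equal n_strains")
    suffix = "hom" if collection == "homozygous" else "het"
    return pd.DataFrame(
        {
            "strain_id": [f"{g}:{suffix}" for g in genes],
            "gene": genes,
            "up_tag": [codes_to_seq(codes[2 * i]) for i in range(n_strains)],
            "down_tag": [codes_to_seq(codes[2 * i + 1]) for i in range(n_strains)],
            "collection": collection,
        }
    )


def tags_frame(catalog: pd.DataFrame) -> pd.DataFrame:
    """Long-form tag table: one row per tag (tag_id, strain_id, kind, seq).

    tag_id is ``<strain_id>:up`` / ``<strain_id>:down``; rows are ordered
    up, down within each catalog strain.
    """
    rows = []
    for r in catalog.itertuples(index=False):
        rows.append((f"{r.strain_id}:up", r.strain_id, "up", r.up_tag))
        rows.append((f"{r.strain_id}:down", r.strain_id, "down", r.down_tag))
    return pd.DataFrame(rows, columns=["tag_id", "strain_id", "kind", "seq"])


# ---------------------------------------------------------------------------
# ground-truth fitness effects

def generate_truth(catalog: pd.DataFrame, *,
                   frac_impaired: float = 0.05,
                   frac_advantaged: float = 0.03,
                   frac_artifact: float = 0.12,
                   effect_scale: float = 0.2,
                   freq_sigma: float = 1.0,
                   seed: int = 0) -> pd.DataFrame:
    """Draw per-strain selection coefficients and artifact flags.

    Gene roles, in draw order (all draws are gene-level, so calling with a
    homozygous and a heterozygous catalog sharing the same genes and seed
    yields consistent truths for the two pools):

    * initial frequencies ~ lognormal(0, freq_sigma), normalised to sum 1;
    * a random gene permutation assigns: one HOG1-like sentinel (lethal
      under both stresses, s_glucose = s_sorbitol = -2, neutral in basal);
      one BUL1-like sentinel (advantaged under both stresses,
      s in [0.13, 0.16], so 10 generations give logFC ~ 1.3-1.6); then
      ``frac_impaired`` impaired, ``frac_advantaged`` advantaged and
      ``frac_artifact`` suppressor-artifact genes, disjointly;
    * impaired genes: affected under both stresses (p=0.5) or one stress
      (p=0.25 each), with s = -|N(effect_scale, effect_scale/2)| shared
      across affected conditions; advantaged genes mirror this with +|..|;
    * suppressor-artifact genes model extragenic suppressors acquired
      during propagation of the homozygous collection: in the homozygous
      pool s_basal = +|N(0.08, 0.03)| (mild advantage, logFC just above 0),
      in the heterozygous pool s_basal = -(0.3 + |N(0.05, 0.03)|) (strong
      impairment, logFC < -3 over 20 generations).

    Returns a DataFrame with columns strain_id, gene, s_basal, s_glucose,
    s_sorbitol, suppressor_artifact, role, initial_frequency.
    """
    for name, f in (("frac_impaired", frac_impaired),
                    ("frac_advantaged", frac_advantaged),
                    ("frac_artifact", frac_artifact)):
        if not 0 <= f <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    if frac_impaired + frac_advantaged + frac_artifact > 1:
        raise ValueError("role fractions must sum to <= 1")
    n = len(catalog)
    collection = catalog["collection"].iloc[0]
    rng = np.random.default_rng(seed)

    freq = rng.lognormal(0.0, freq_sigma, size=n)
    freq /= freq.sum()

    perm = rng.permutation(n)
    role = np.full(n, "neutral", dtype=object)
    s_basal = np.zeros(n)
    s_glu = np.zeros(n)
    s_sor = np.zeros(n)
    artifact = np.zeros(n, dtype=bool)

    cursor = 0
    if n >= 1:
        hog = perm[cursor]
        role[hog] = "hog1_like"
        s_glu[hog] = s_sor[hog] = -2.0
        # quality-control reference strains enter the pool at representative
        # abundance, so their recovery reflects the method, not the draw
        freq[hog] = freq.mean()
        cursor += 1
    if n >= 2:
        bul = perm[cursor]
        role[bul] = "bul1_like"
        s_glu[bul] = s_sor[bul] = rng.uniform(0.13, 0.16)
        freq[bul] = freq.mean()
        cursor += 1
    freq /= freq.sum()

    n_imp = int(round(frac_impaired * n))
    n_adv = int(round(frac_advantaged * n))
    n_art = int(round(frac_artifact * n))
    n_imp = min(n_imp, n - cursor)
    imp_idx = perm[cursor:cursor + n_imp]
    cursor += n_imp
    n_adv = min(n_adv, n - cursor)
    adv_idx = perm[cursor:cursor + n_adv]
    cursor += n_adv
    n_art = min(n_art, n - cursor)
    art_idx = perm[cursor:cursor + n_art]

    for idx, sign, label in ((imp_idx, -1.0, "impaired"), (adv_idx, 1.0, "advantaged")):
        modes = rng.choice(3, size=len(idx), p=[0.5, 0.25, 0.25])  # both/glu/sor
        mags = sign * np.abs(rng.normal(effect_scale, effect_scale / 2, size=len(idx)))
        for i, mode, mag in zip(idx, modes, mags):
            role[i] = label
            if mode in (0, 1):
                s_glu[i] = mag
            if mode in (0, 2):
                s_sor[i] = mag

    hom_drift = np.abs(rng.normal(0.08, 0.03, size=len(art_idx)))
    het_deficit = 0.3 + np.abs(rng.normal(0.05, 0.03, size=len(art_idx)))
    role[art_idx] = "artifact"
    artifact[art_idx] = True
    if collection == "homozygous":
        s_basal[art_idx] = hom_drift
    else:
        s_basal[art_idx] = -het_deficit

    return pd.DataFrame(
        {
            "strain_id": catalog["strain_id"].to_numpy(),
            "gene": catalog["gene"].to_numpy(),
            "s_basal": s_basal,
            "s_glucose": s_glu,
            "s_sorbitol": s_sor,
            "suppressor_artifact": artifact,
            "role": role,
            "initial_frequency": freq,
        }
    )


# ---------------------------------------------------------------------------
# competition dynamics

@dataclass
class CompetitionCounts:
    """Expected strain frequencies plus sampled per-tag replicate counts."""

    expected_freq: pd.Series          # per strain, after G generations
    tag_counts: pd.DataFrame          # tags x replicates, integer


def expected_frequencies(truth: pd.DataFrame, condition: str,
                         generations: float) -> pd.Series:
    """Deterministic strain frequencies after exponential competition.

    f_i(G) = f_i(0) * 2^(G*s_i) / sum_j f_j(0) * 2^(G*s_j).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    if generations < 0:
        raise ValueError("generations must be >= 0")
    s = np.zeros(len(truth)) if condition == "t0" else truth[f"s_{condition}"].to_numpy()
    w = truth["initial_frequency"].to_numpy() * np.exp2(generations * s)
    return pd.Series(w / w.sum(), index=truth["strain_id"].to_numpy(), name="freq")


def simulate_competition(catalog: pd.DataFrame, truth: pd.DataFrame,
                         condition: str, generations: float, depth: int,
                         n_replicates: int = 3, seed: int = 0, *,
                         dispersion: float = 0.05,
                         tag_bias_sigma: float = 0.3) -> CompetitionCounts:
    """Simulate tag counts for one condition's biological replicates.

    Expected strain frequencies follow :func:`expected_frequencies`. Each
    strain's abundance is split between its up- and down-tag with a per-tag
    lognormal(0, tag_bias_sigma) amplification bias (one draw per tag,
    shared across replicates, emulating PCR efficiency differences). Each
    replicate multiplies strain abundances by an independent
    Gamma(1/dispersion, mean 1) factor — biological replicate noise that
    makes counts negative-binomial-like with dispersion ~``dispersion`` —
    and then draws a single multinomial of size ``depth`` over all tags.

    Draw order: tag bias (2n), then per replicate gamma (n) + multinomial.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = np.random.default_rng(seed)
    freq = expected_frequencies(truth, condition, generations)
    tags = tags_frame(catalog)
    n = len(catalog)

    bias = rng.lognormal(0.0, tag_bias_sigma, size=2 * n)
    b_up, b_dn = bias[0::2], bias[1::2]
    share_up = b_up / (b_up + b_dn)
    f = freq.to_numpy()
    e_tag = np.empty(2 * n)
    e_tag[0::2] = f * share_up
    e_tag[1::2] = f * (1.0 - share_up)

    cols = {}
    for r in range(1, n_replicates + 1):
        if dispersion > 0:
            g = rng.gamma(1.0 / dispersion, scale=dispersion, size=n)
        else:
            g = np.ones(n)
        p = e_tag * np.repeat(g, 2)
        p = p / p.sum()
        cols[f"rep{r}"] = rng.multinomial(depth, p)
    tag_counts = pd.DataFrame(cols, index=pd.Index(tags["tag_id"], name="tag_id"))
    return CompetitionCounts(expected_freq=freq, tag_counts=tag_counts)


def aggregate_tag_counts(tag_counts: pd.DataFrame, catalog: pd.DataFrame) -> pd.DataFrame:
    """Sum simulated up-/down-tag count rows into per-strain rows."""
    tags = tags_frame(catalog).set_index("tag_id")
    strain = tags.loc[tag_counts.index, "strain_id"]
    out = tag_counts.groupby(strain.to_numpy(), sort=False).sum()
    out = out.reindex(catalog["strain_id"], fill_value=0)
    out.index.name = "strain_id"
    return out


def simulate_contrast_counts(catalog: pd.DataFrame, truth: pd.DataFrame,
                             cond_a: str, cond_b: str, generations: float,
                             depth: int, n_replicates: int = 3, seed: int = 0,
                             dispersion: float = 0.05,
                             tag_bias_sigma: float = 0.3):
    """Strain-level counts for a two-condition contrast (convenience wrapper).

    Simulates both conditions with independent sub-streams of ``seed`` and
    returns ``(counts, samples_a, samples_b)`` where counts is a strain ×
    sample DataFrame with columns ``<cond>_<rep>``.
    """
    ss_a, ss_b = np.random.SeedSequence(seed).spawn(2)
    cols = {}
    names = {}
    for cond, child in ((cond_a, ss_a), (cond_b, ss_b)):
        G = 0.0 if cond == "t0" else generations
        sim = simulate_competition(catalog, truth, cond, G, depth, n_replicates,
                                   seed=child, dispersion=dispersion,
                                   tag_bias_sigma=tag_bias_sigma)
        strain = aggregate_tag_counts(sim.tag_counts, catalog)
        names[cond] = [f"{cond}_{r}" for r in range(1, n_replicates + 1)]
        for name, rep in zip(names[cond], strain.columns):
            cols[name] = strain[rep]
    return pd.DataFrame(cols), names[cond_a], names[cond_b]


# ---------------------------------------------------------------------------
# sample sheets and reads

def generate_indices(n: int, seed: int = 0, *,
                     min_distance: int = MIN_INDEX_DISTANCE,
                     max_tries: int = 10000) -> list[str]:
    """Draw n 6-mer multiplex indices pairwise Hamming >= min_distance apart."""
    rng = np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    tries = 0
    while len(chosen) < n:
        cand = rng.integers(0, 4, size=INDEX_LENGTH, dtype=np.uint8)
        if all(int((cand != c).sum()) >= min_distance for c in chosen):
            chosen.append(cand)
        tries += 1
        if tries > max_tries:
            raise RuntimeError(f"could not draw {n} indices at distance >= {min_distance}")
    return [codes_to_seq(c) for c in chosen]


def make_samplesheet(collection: str = "homozygous", n_replicates: int = 3,
                     generations: float | None = None, seed: int = 0) -> pd.DataFrame:
    """Sample sheet for one collection: t0 plus triplicate competitions.

    ``generations`` defaults to the experimental design: 10 for the
    homozygous pool, 20 for the heterozygous pool; t0 samples have 0.
    """
    if generations is None:
        generations = 10.0 if collection == "homozygous" else 20.0
    prefix = "hom" if collection == "homozygous" else "het"
    rows = []
    for cond in CONDITIONS:
        for rep in range(1, n_replicates + 1):
            rows.append((f"{prefix}_{cond}_{rep}", cond, rep,
                         0.0 if cond == "t0" else generations))
    sheet = pd.DataFrame(rows, columns=["sample_id", "condition", "replicate", "generations"])
    sheet.insert(1, "index", generate_indices(len(sheet), seed))
    return sheet


def simulate_reads(tag_counts: pd.DataFrame, catalog: pd.DataFrame,
                   samplesheet: pd.DataFrame, path,
                   layout: ReadLayout = DEFAULT_LAYOUT,
                   error_rate: float = 0.0, seed: int = 0) -> None:
    """Write a multiplexed gzipped FASTQ realising a tag count table.

    ``tag_counts`` columns must match ``samplesheet.sample_id``; exactly
    sum(counts) reads are emitted. Each read is index + common primer (up or
    down, by tag kind) + 20-mer tag + random filler to ``layout.read_length``,
    then independent per-base substitution (to a different base) with
    probability ``error_rate``. Quality is a constant 'I' line; the counter
    never reads qualities. Draw order, per sample in sheet order: filler
    matrix, error mask, error offsets.
    """
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    missing = set(tag_counts.index) - set(tags_frame(catalog)["tag_id"])
    if missing:
        raise ValueError(f"tag_counts contains tags absent from catalog: {sorted(missing)[:3]}")
    rng = np.random.default_rng(seed)
    tags = tags_frame(catalog).set_index("tag_id")
    L = layout.read_length
    qual = b"I" * L

    prefix_codes = {}
    for tag_id, row in tags.iterrows():
        primer = layout.up_common_primer if row["kind"] == "up" else layout.down_common_primer
        prefix_codes[tag_id] = seq_to_codes(primer + row["seq"])

    # mtime=0 keeps the gzip header byte-stable across reruns
    with open(path, "wb") as raw, gzip.GzipFile(
        filename="", mode="wb", fileobj=raw, compresslevel=1, mtime=0
    ) as fh:
        for srow in samplesheet.itertuples(index=False):
            if srow.sample_id not in tag_counts.columns:
                continue
            counts = tag_counts[srow.sample_id]
            counts = counts[counts > 0]
            total = int(counts.sum())
            if total == 0:
                continue
            idx_codes = seq_to_codes(srow.index)
            mat = rng.integers(0, 4, size=(total, L), dtype=np.uint8)
            mat[:, :layout.index_length] = idx_codes
            pos = 0
            for tag_id, c in counts.items():
                body = prefix_codes[tag_id]
                mat[pos:pos + c, layout.index_length:layout.index_length + body.size] = body
                pos += int(c)
            if error_rate > 0:
                mask = rng.random(size=mat.shape) < error_rate
                shifts = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
                mat[mask] = (mat[mask] + shifts) % 4
            seqs = np.ascontiguousarray(BASE_BYTES[mat]).view(f"S{L}").ravel()
            name = srow.sample_id.encode()
            fh.write(b"".join(
                b"@%s:%d\n%s\n+\n%s\n" % (name, i, seqs[i], qual)
                for i in range(total)
            ))


# ---------------------------------------------------------------------------
# annotation

def generate_annotation(catalog: pd.DataFrame, truth: pd.DataFrame, *,
                        n_terms: int = 50,
                        planted_term_size: int = 20,
                        planted_overlap: int = 15,
                        term_size_range: tuple[int, int] = (5, 40),
                        seed: int = 0) -> pd.DataFrame:
    """Flat gene→term annotation with one term planted among impaired genes.

    The planted term (id ``T0000:planted``) contains ``planted_overlap``
    genes drawn from the truth's stress-impaired genes (roles impaired /
    hog1_like) and the remainder from unaffected genes; the other
    ``n_terms - 1`` terms get uniformly sized random gene sets — the null
    background for enrichment testing. Returns a two-column DataFrame
    (gene, term), one pair per row.
    """
    genes = catalog["gene"].to_numpy()
    impaired = truth.loc[truth["role"].isin(["impaired", "hog1_like"]), "gene"].to_numpy()
    others = np.setdiff1d(genes, impaired)
    if planted_term_size > len(genes):
        raise ValueError("planted_term_size exceeds number of genes")
    if planted_overlap > min(planted_term_size, len(impaired)):
        raise ValueError("requested planted overlap impossible")
    if planted_term_size - planted_overlap > len(others):
        raise ValueError("not enough unaffected genes for planted term")
    rng = np.random.default_rng(seed)
    rows = []
    in_term = list(rng.choice(impaired, size=planted_overlap, replace=False))
    in_term += list(rng.choice(others, size=planted_term_size - planted_overlap,
                               replace=False))
    rows += [(g, "T0000:planted") for g in in_term]
    lo, hi = term_size_range
    for t in range(1, n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=min(size, len(genes)), replace=False)
        rows += [(g, f"T{t:04d}") for g in members]
    return pd.DataFrame(rows, columns=["gene", "term"])
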