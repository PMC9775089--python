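"""De novo motif elicitation and PWM comparison.

Discovery uses a one-occurrence-per-sequence (OOPS) expectation-maximisation
model scanned over candidate widths, with starts seeded from sampled words
and both strands considered.  Column probabilities are estimated with a
pseudocount of 0.25 per base, which makes each EM iteration a MAP update
under a Dirichlet prior; the penalised objective is therefore non-decreasing
and is asserted as such on every run.

Width selection uses a BIC-style score (log-likelihood ratio penalised by
1.5 * width * ln(n_sequences)).  A discovered motif is flagged significant
only when its log-likelihood ratio exceeds the best value obtained on
``n_null`` letter-shuffled copies of the input - a pragmatic stand-in for a
formal E-value.

Comparison against a motif database scores every offset with at least four
overlapping columns in both orientations by the mean per-column Pearson
correlation, with an empirical column-shuffle null and BH correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MotifModel",
    "MotifMatch",
    "Site",
    "extract_upstream",
    "discover_motifs",
    "score_sites",
    "compare_motifs",
    "pwm_from_consensus",
    "read_fasta",
    "write_fasta",
    "read_jaspar_pfm",
    "write_jaspar_pfm",
    "read_meme",
    "write_meme",
]

ALPHABET = "ACGT"
_IDX = {c: i for i, c in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")
UNIFORM_BG = np.full(4, 0.25)


def encode(seq: str) -> np.ndarray:
    """Map a sequence to indices 0-3 (A, C, G, T); everything else to 4."""
    return np.array([_IDX.get(c, 4) for c in seq.upper()], dtype=np.int8)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class Site(NamedTuple):
    seq_id: str
    offset: int
    strand: str
    score: float


@dataclass
class MotifModel:
    """Position weight matrix (4 x width, rows A/C/G/T) with site annotations."""

    name: str
    pwm: np.ndarray
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BG.copy())
    sites: list = field(default_factory=list)
    llr: float = 0.0
    objective_history: list = field(default_factory=list)
    significant: bool | None = None

    def __post_init__(self) -> None:
        self.pwm = np.asarray(self.pwm, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.pwm.ndim != 2 or self.pwm.shape[0] != 4 or self.pwm.shape[1] < 1:
            raise ValueError("pwm must be a 4 x width matrix")
        if not np.allclose(self.pwm.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError("every pwm column must sum to 1")
        if self.background.shape != (4,) or not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must be a 4-vector summing to 1")

    @property
    def width(self) -> int:
        return int(self.pwm.shape[1])

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.pwm.argmax(axis=0))

    def information_content(self) -> np.ndarray:
        """Per-column 2 - entropy, in bits."""
        p = np.clip(self.pwm, 1e-12, None)
        return 2.0 + (p * np.log2(p)).sum(axis=0)

    def log_odds(self) -> np.ndarray:
        """5 x width log(pwm / background); the 5th row (ambiguous base) is 0."""
        lo = np.log(np.clip(self.pwm, 1e-12, None) / self.background[:, None])
        return np.vstack([lo, np.zeros(self.width)])

    def reverse_complemented(self) -> "MotifModel":
        return MotifModel(
            self.name + "_rc", self.pwm[::-1, ::-1].copy(), self.background.copy()
        )


def pwm_from_consensus(consensus: str, strength: float = 0.9) -> np.ndarray:
    """High-information PWM placing ``strength`` on each consensus base."""
    if not 0.25 <= strength <= 1.0:
        raise ValueError("strength must be in [0.25, 1]")
    w = len(consensus)
    pwm = np.full((4, w), (1.0 - strength) / 3.0)
    for k, c in enumerate(consensus.upper()):
        pwm[_IDX[c], k] = strength
    return pwm


# --------------------------------------------------------------- extraction


def extract_upstream(genome, bed_path, flank: int = 1000) -> list[tuple[str, str]]:
    """Strand-aware fixed-length upstream windows from a genome FASTA + BED.

    BED coordinates are 0-based half-open.  A + strand gene [s, e) yields
    [s - flank, s); a - strand gene yields [e, e + flank) reverse
    complemented.  Windows are truncated at chromosome ends with a warning.
    """
    from pyfaidx import Fasta

    fa = genome if not isinstance(genome, (str, Path)) else Fasta(str(genome))
    records: list[tuple[str, str]] = []
    with Path(bed_path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 and parts[3] != "." else f"{chrom}:{start}-{end}"
            strand = parts[5] if len(parts) > 5 else "+"
            if chrom not in fa:
                raise KeyError(f"chromosome {chrom!r} not present in genome FASTA")
            clen = len(fa[chrom])
            if strand == "-":
                a, b = end, min(end + flank, clen)
            else:
                a, b = max(start - flank, 0), start
            if b - a < flank:
                warnings.warn(
                    f"upstream window for {name} truncated to {b - a} bases at a "
                    "chromosome end",
                    stacklevel=2,
                )
            if b <= a:
                continue
            seq = str(fa[chrom][a:b])
            if strand == "-":
                seq = reverse_complement(seq)
            records.append((name, seq.upper()))
    return records


# ------------------------------------------------------------------ scanning


def _window_scores(x: np.ndarray, lo_pad: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Forward and reverse-strand log-odds scores for every offset of x."""
    w = lo_pad.shape[1]
    win = sliding_window_view(x, w)
    cols = np.arange(w)
    fwd = lo_pad[win, cols].sum(axis=1)
    # a minus-strand site at offset j is the reverse complement of the window
    lo_rc = np.vstack([lo_pad[:4][::-1, ::-1], np.zeros(w)])
    rev = lo_rc[win, cols].sum(axis=1)
    return fwd, rev


def score_sites(model: MotifModel, seq: str) -> Site:
    """Best log-odds site over all offsets and both strands.

    Ties break to the smallest offset with forward strand preferred.
    Ambiguous bases contribute log-odds 0.
    """
    x = encode(seq)
    if x.size < model.width:
        raise ValueError("sequence shorter than motif width")
    fwd, rev = _window_scores(x, model.log_odds())
    best = max(fwd.max(), rev.max())
    fhit = np.nonzero(fwd >= best)[0]
    if fhit.size:
        return Site("", int(fhit[0]), "+", float(best))
    rhit = np.nonzero(rev >= best)[0]
    return Site("", int(rhit[0]), "-", float(best))


# ---------------------------------------------------------------------- EM


def _init_pwm(x: np.ndarray, offset: int, w: int, match: float = 0.7) -> np.ndarray:
    pwm = np.full((4, w), (1.0 - match) / 3.0)
    for k in range(w):
        b = x[offset + k]
        if b < 4:
            pwm[b, k] = match
        else:
            pwm[:, k] = 0.25
    return pwm / pwm.sum(axis=0, keepdims=True)


def _oops_em(
    xs: Sequence[np.ndarray],
    init_pwm: np.ndarray,
    background: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-6,
    pseudocount: float = 0.25,
):
    """One-occurrence-per-sequence EM over both strands.

    Returns (pwm, llr, per-sequence posteriors argmax sites, objective history).
    The tracked objective is the OOPS log-likelihood ratio plus the Dirichlet
    prior term implied by the pseudocount; it must be non-decreasing.
    """
    w = init_pwm.shape[1]
    windows = [sliding_window_view(x, w) for x in xs]
    comp_windows = [np.where(win == 4, 4, 3 - win) for win in windows]
    cols = np.arange(w)
    rcols = w - 1 - cols
    pwm = init_pwm.copy()
    history: list[float] = []
    prev = -np.inf
    llr = 0.0
    for _ in range(max_iter):
        lo = np.log(np.clip(pwm, 1e-12, None) / background[:, None])
        lo_pad = np.vstack([lo, np.zeros(w)])
        lo_rc = np.vstack([lo[::-1, ::-1], np.zeros(w)])
        counts = np.zeros((5, w))
        llr = 0.0
        for win, cwin in zip(windows, comp_windows):
            sf = lo_pad[win, cols].sum(axis=1)
            sr = lo_rc[win, cols].sum(axis=1)
            s = np.concatenate([sf, sr])
            smax = s.max()
            e = np.exp(s - smax)
            z = e.sum()
            llr += smax + np.log(z) - np.log(s.size)
            gamma = e / z
            gf = gamma[: sf.size]
            gr = gamma[sf.size :]
            np.add.at(counts, (win, np.broadcast_to(cols, win.shape)), gf[:, None])
            np.add.at(counts, (cwin, np.broadcast_to(rcols, cwin.shape)), gr[:, None])
        objective = llr + pseudocount * float(np.log(np.clip(pwm, 1e-12, None)).sum())
        if objective < prev - 1e-8 * (1.0 + abs(prev)):
            raise RuntimeError("EM objective decreased; numerical failure")
        history.append(objective)
        counts4 = counts[:4] + pseudocount
        pwm = counts4 / counts4.sum(axis=0, keepdims=True)
        if np.isfinite(prev) and abs(objective - prev) <= tol * (1.0 + abs(prev)):
            break
        prev = objective
    # final site assignments and LLR under the converged model
    lo = np.log(np.clip(pwm, 1e-12, None) / background[:, None])
    lo_pad = np.vstack([lo, np.zeros(w)])
    lo_rc = np.vstack([lo[::-1, ::-1], np.zeros(w)])
    sites = []
    llr = 0.0
    for win in windows:
        sf = lo_pad[win, cols].sum(axis=1)
        sr = lo_rc[win, cols].sum(axis=1)
        s = np.concatenate([sf, sr])
        smax = s.max()
        llr += smax + np.log(np.exp(s - smax).sum()) - np.log(s.size)
        if sf.max() >= sr.max():
            sites.append((int(np.argmax(sf)), "+", float(sf.max())))
        else:
            sites.append((int(np.argmax(sr)), "-", float(sr.max())))
    return pwm, float(llr), sites, history


def _pooled_background(xs: Iterable[np.ndarray]) -> np.ndarray:
    counts = np.zeros(4)
    for x in xs:
        counts += np.bincount(x[x < 4], minlength=4)
    total = counts.sum()
    return counts / total if total else UNIFORM_BG.copy()


def _fit_width(xs, ids, w, background, rng, n_starts, max_iter, n_candidates=30):
    """Best EM fit at one width.

    Starts are screened: ``n_candidates`` sampled words each get two EM
    iterations, and the ``n_starts`` most promising are optimised fully.
    """
    usable = [(i, x) for i, x in enumerate(xs) if x.size >= w]
    if len(usable) < 2:
        return None
    sub = [x for _, x in usable]
    scored = []
    for _ in range(max(n_candidates, n_starts)):
        si = int(rng.integers(len(sub)))
        off = int(rng.integers(sub[si].size - w + 1))
        init = _init_pwm(sub[si], off, w)
        probe = _oops_em(sub, init, background, max_iter=2)
        scored.append((probe[1], init))
    scored.sort(key=lambda t: -t[0])
    best = None
    for _, init in scored[:n_starts]:
        fit = _oops_em(sub, init, background, max_iter=max_iter)
        if best is None or fit[1] > best[1]:
            best = fit
    # shift refinement: converged models that straddle the true site by a
    # column are a common EM attractor; retry from +/-1-shifted versions
    for _ in range(3):
        improved = False
        for shift in (-1, 1):
            pwm = best[0]
            bgcol = background[:, None]
            init = (
                np.hstack([pwm[:, 1:], bgcol]) if shift > 0
                else np.hstack([bgcol, pwm[:, :-1]])
            )
            fit = _oops_em(sub, init, background, max_iter=max_iter)
            if fit[1] > best[1] + 1e-6:
                best = fit
                improved = True
        if not improved:
            break
    pwm, llr, raw_sites, history = best
    sites = [
        Site(ids[usable[k][0]], off, strand, score)
        for k, (off, strand, score) in enumerate(raw_sites)
    ]
    return pwm, llr, sites, history


def discover_motifs(
    seqs: Sequence[tuple[str, str]],
    wmin: int = 6,
    wmax: int = 20,
    n_motifs: int = 2,
    seed: int = 0,
    n_starts: int = 3,
    n_null: int = 20,
    background: np.ndarray | None = None,
    max_iter: int = 100,
) -> list[MotifModel]:
    """Elicit up to ``n_motifs`` motifs, one occurrence per sequence.

    Per candidate width the best of ``n_starts`` EM runs is kept; the width
    with the highest BIC-penalised log-likelihood ratio wins.  After each
    motif its sites are masked (replaced by ambiguous bases) and the search
    repeats.  Sequences shorter than ``wmin`` are skipped with a warning.
    """
    if not 1 <= wmin <= wmax:
        raise ValueError("need 1 <= wmin <= wmax")
    ids, xs = [], []
    for name, seq in seqs:
        x = encode(seq)
        if x.size < wmin:
            warnings.warn(f"sequence {name!r} shorter than wmin={wmin}; skipped", stacklevel=2)
            continue
        ids.append(name)
        xs.append(x.copy())
    if len(xs) < 2:
        raise ValueError("need at least 2 sequences of length >= wmin")
    if background is None:
        background = _pooled_background(xs)
    background = np.asarray(background, dtype=float)
    rng = np.random.default_rng(seed)
    # complexity penalty per column: BIC-style, with the effective sample size
    # taken as the number of scanned candidate positions (both strands), which
    # accounts for the latent-alignment freedom of the site model
    n_positions = 2 * sum(max(x.size - wmin + 1, 1) for x in xs)
    penalty = 1.5 * np.log(n_positions)
    models: list[MotifModel] = []
    for m in range(n_motifs):
        best_fit, best_w, best_score = None, None, -np.inf
        for w in range(wmin, wmax + 1):
            fit = _fit_width(xs, ids, w, background, rng, n_starts, max_iter)
            if fit is None:
                continue
            score = fit[1] - w * penalty
            if score > best_score:
                best_fit, best_w, best_score = fit, w, score
        if best_fit is None:
            break
        pwm, llr, sites, history = best_fit
        significant = None
        if n_null > 0:
            null_best = -np.inf
            for _ in range(n_null):
                shuffled = [rng.permutation(x) for x in xs]
                nf = _fit_width(
                    shuffled, ids, best_w, background, rng, max(2, n_starts - 1), 50
                )
                if nf is not None:
                    null_best = max(null_best, nf[1])
            significant = bool(llr > null_best)
        models.append(
            MotifModel(
                name=f"motif_{m + 1}",
                pwm=pwm,
                background=background,
                sites=sites,
                llr=llr,
                objective_history=history,
                significant=significant,
            )
        )
        for site in sites:  # mask before searching for the next motif
            x = xs[ids.index(site.seq_id)]
            x[site.offset : site.offset + best_w] = 4
    return models


# --------------------------------------------------------------- comparison


def _column_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation between every column of a and every column of b."""
    ac = a - a.mean(axis=0, keepdims=True)
    bc = b - b.mean(axis=0, keepdims=True)
    asd = np.sqrt((ac**2).sum(axis=0))
    bsd = np.sqrt((bc**2).sum(axis=0))
    out = np.zeros((a.shape[1], b.shape[1]))
    ok_a = asd > 1e-12
    ok_b = bsd > 1e-12
    num = ac.T @ bc
    with np.errstate(invalid="ignore", divide="ignore"):
        out[np.ix_(ok_a, ok_b)] = (
            num[np.ix_(ok_a, ok_b)] / np.outer(asd[ok_a], bsd[ok_b])
        )
    # two flat columns are identical up to their common value: treat as r = 1
    both_flat = np.outer(~ok_a, ~ok_b)
    if both_flat.any():
        eq = np.isclose(a.mean(axis=0)[:, None], b.mean(axis=0)[None, :], atol=1e-9)
        out[both_flat & eq] = 1.0
    return np.clip(out, -1.0, 1.0)


def _best_offset(C: np.ndarray, min_overlap: int) -> tuple[float, int]:
    """Best mean diagonal of C over all alignments with enough overlap."""
    wq, wd = C.shape
    best, best_off = -np.inf, 0
    for off in range(-(wq - 1), wd):
        qi = np.arange(max(0, -off), min(wq, wd - off))
        if qi.size < min_overlap:
            continue
        sim = float(C[qi, qi + off].mean())
        if sim > best:
            best, best_off = sim, off
    return best, best_off


@dataclass
class MotifMatch:
    query: str
    target: str
    offset: int
    orientation: str  # forward | reverse-complement
    similarity: float
    p: float
    p_adj: float = float("nan")


def compare_motifs(
    query: MotifModel,
    database: Sequence[MotifModel],
    n_null: int = 1000,
    seed: int = 0,
    min_overlap: int = 4,
) -> list[MotifMatch]:
    """Align the query PWM to every database PWM in both orientations.

    Similarity is the mean per-column Pearson correlation over the best
    offset with at least ``min_overlap`` overlapping columns.  The empirical
    p-value shuffles the query's column order ``n_null`` times; BH correction
    runs across the database.  Results are sorted by p, then by similarity.
    """
    if not len(database):
        raise ValueError("motif database is empty")
    rng = np.random.default_rng(seed)
    perms = [rng.permutation(query.width) for _ in range(n_null)]
    matches = []
    for db in database:
        cf = _column_corr(query.pwm, db.pwm)
        cr = _column_corr(query.pwm, db.pwm[::-1, ::-1])
        sf, off_f = _best_offset(cf, min_overlap)
        sr, off_r = _best_offset(cr, min_overlap)
        if sf >= sr:
            sim, off, orient = sf, off_f, "forward"
        else:
            sim, off, orient = sr, off_r, "reverse-complement"
        if not np.isfinite(sim):
            matches.append(MotifMatch(query.name, db.name, 0, "forward", float("nan"), 1.0))
            continue
        exceed = 0
        for perm in perms:
            nf, _ = _best_offset(cf[perm], min_overlap)
            nr, _ = _best_offset(cr[perm], min_overlap)
            if max(nf, nr) >= sim:
                exceed += 1
        p = (1.0 + exceed) / (n_null + 1.0)
        matches.append(MotifMatch(query.name, db.name, off, orient, float(sim), float(p)))
    padj = multipletests([m.p for m in matches], method="fdr_bh")[1]
    for m, q in zip(matches, padj):
        m.p_adj = float(q)
    matches.sort(key=lambda m: (m.p, -(m.similarity if np.isfinite(m.similarity) else -2.0), m.target))
    return matches


# ---------------------------------------------------------------------- I/O


def read_fasta(path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path, line_width: int = 70) -> None:
    with Path(path).open("w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


def read_jaspar_pfm(path, pseudocount: float = 0.25) -> list[MotifModel]:
    """Read JASPAR-style PFM text; counts become probabilities with a pseudocount."""
    from Bio import motifs as bio_motifs

    models = []
    with Path(path).open() as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([list(m.counts[b]) for b in ALPHABET], dtype=float)
            counts += pseudocount
            pwm = counts / counts.sum(axis=0, keepdims=True)
            name = m.matrix_id or m.name
            if m.name and m.matrix_id:
                name = f"{m.matrix_id} {m.name}"
            models.append(MotifModel(name=name, pwm=pwm))
    return models


def write_jaspar_pfm(models: Iterable[MotifModel], path, scale: int = 100) -> None:
    with Path(path).open("w") as fh:
        for model in models:
            fh.write(f">{model.name}\n")
            counts = model.pwm * scale
            for i, base in enumerate(ALPHABET):
                row = " ".join(f"{v:.2f}" for v in counts[i])
                fh.write(f"{base} [ {row} ]\n")


def write_meme(models: Iterable[MotifModel], path) -> None:
    """Minimal MEME motif text format."""
    models = list(models)
    bg = models[0].background if models else UNIFORM_BG
    with Path(path).open("w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.6f}" for b, f in zip(ALPHABET, bg)) + "\n\n")
        for model in models:
            fh.write(f"MOTIF {model.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {model.width} "
                f"nsites= {max(len(model.sites), 1)} E= "
                f"{0.0 if model.significant else 1.0}\n"
            )
            for col in model.pwm.T:
                fh.write(" " + " ".join(f"{v:.6f}" for v in col) + "\n")
            fh.write("\n")


def read_meme(path) -> list[MotifModel]:
    models = []
    bg = UNIFORM_BG.copy()
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            parts = lines[i + 1].split()
            bg = np.array([float(parts[k]) for k in (1, 3, 5, 7)])
            i += 2
            continue
        if line.startswith("MOTIF"):
            name = line.split(None, 1)[1].strip()
            i += 1
            while not lines[i].strip().startswith("letter-probability matrix"):
                i += 1
            w = int(lines[i].split("w=")[1].split()[0])
            cols = []
            for k in range(w):
                cols.append([float(v) for v in lines[i + 1 + k].split()])
            models.append(MotifModel(name=name, pwm=np.array(cols).T, background=bg.copy()))
            i += w + 1
            continue
        i += 1
    return models
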