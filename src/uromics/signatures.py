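"""Trinucleotide (96-class) mutation catalogs and NMF signature extraction.

Single-base substitutions are annotated with their immediate 5' and 3'
neighbours and reported on the pyrimidine strand, giving 6 substitution
classes x 16 flanking contexts = 96 categories.  Per-sample category counts
form a catalog that is factorised by non-negative matrix factorisation
(generalized Kullback-Leibler objective, multiplicative updates) into
signature profiles and per-sample exposures; extracted signatures are
matched to a reference catalog by cosine similarity and placed on a Ward
(ward.D2) dendrogram of 1 - cosine dissimilarities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .variants import VariantRecord

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: The six pyrimidine-strand substitution classes, in canonical order.
SUBSTITUTION_CLASSES: tuple[tuple[str, str], ...] = (
    ("C", "A"), ("C", "G"), ("C", "T"), ("T", "A"), ("T", "C"), ("T", "G"),
)


def _build_categories() -> tuple[str, ...]:
    cats = []
    for ref, alt in SUBSTITUTION_CLASSES:
        for five in "ACGT":
            for three in "ACGT":
                cats.append(f"{five}[{ref}>{alt}]{three}")
    return tuple(cats)


#: Fixed 96-category ordering: classes C>A, C>G, C>T, T>A, T>C, T>G; flanking
#: contexts alphabetical (5' major, 3' minor) within each class.
CATEGORIES_96: tuple[str, ...] = _build_categories()
_CATEGORY_INDEX: dict[str, int] = {c: i for i, c in enumerate(CATEGORIES_96)}


class UnclassifiableContext(ValueError):
    """Raised when a trinucleotide context cannot be assigned a category."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def classify_context(ref_triplet: str, ref_allele: str, alt_allele: str) -> str:
    """Map a mutated trinucleotide to its pyrimidine-strand category label.

    The middle base of ``ref_triplet`` must equal ``ref_allele``.  If the
    reference allele is a purine (A/G), the triplet and both alleles are
    reverse-complemented first, so every substitution lands on one of the 96
    pyrimidine-centred labels.
    """
    if len(ref_triplet) != 3:
        raise UnclassifiableContext(f"triplet must have length 3, got {ref_triplet!r}")
    triplet = ref_triplet.upper()
    ref = ref_allele.upper()
    alt = alt_allele.upper()
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise UnclassifiableContext(f"need single differing alleles, got {ref!r}>{alt!r}")
    if any(b not in "ACGT" for b in triplet + ref + alt):
        raise UnclassifiableContext(f"non-ACGT base in {triplet!r} {ref!r}>{alt!r}")
    if triplet[1] != ref:
        raise UnclassifiableContext(
            f"middle base of {triplet!r} does not match ref allele {ref!r}"
        )
    if ref in "AG":  # purine: report on the opposite strand
        triplet = reverse_complement(triplet)
        ref = ref.translate(_COMPLEMENT)
        alt = alt.translate(_COMPLEMENT)
    return f"{triplet[0]}[{ref}>{alt}]{triplet[2]}"


@dataclass
class MutationCatalog:
    """Per-sample counts over the 96 trinucleotide substitution categories.

    ``counts`` is a samples x 96 integer DataFrame whose columns follow
    :data:`CATEGORIES_96`; ``n_excluded`` tallies SNVs that could not be
    classified (boundary positions, non-ACGT context, reference mismatches).
    """

    counts: pd.DataFrame
    n_excluded: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if tuple(self.counts.columns) != CATEGORIES_96:
            raise ValueError("catalog columns must follow the fixed 96-category ordering")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("catalog counts must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    def matrix(self) -> np.ndarray:
        """96 x samples array (categories as rows), for factorisation."""
        return self.counts.to_numpy().T.astype(float)


def build_catalog(
    variants_by_sample: Mapping[str, Sequence[VariantRecord]],
    reference: Mapping[str, str] | str,
) -> MutationCatalog:
    """Count each sample's SNVs into the 96 categories.

    ``reference`` maps contig name -> sequence (a bare string is treated as a
    single-contig reference matching any contig name).  Indels, boundary
    positions, ambiguous contexts and reference-mismatching records are
    excluded and counted per sample, never raised.
    """
    samples = list(variants_by_sample)
    counts = np.zeros((len(samples), 96), dtype=int)
    excluded: dict[str, int] = {}
    for si, sample in enumerate(samples):
        n_bad = 0
        for rec in variants_by_sample[sample]:
            if rec.variant_class != "SNV":
                n_bad += 1
                continue
            seq = reference if isinstance(reference, str) else reference.get(rec.contig)
            if seq is None or not (2 <= rec.pos <= len(seq) - 1):
                n_bad += 1
                continue
            triplet = seq[rec.pos - 2 : rec.pos + 1].upper()
            if triplet[1] != rec.ref_allele.upper():
                n_bad += 1
                continue
            try:
                label = classify_context(triplet, rec.ref_allele, rec.alt_allele)
            except UnclassifiableContext:
                n_bad += 1
                continue
            counts[si, _CATEGORY_INDEX[label]] += 1
        if n_bad:
            excluded[sample] = n_bad
    frame = pd.DataFrame(counts, index=samples, columns=list(CATEGORIES_96))
    return MutationCatalog(counts=frame, n_excluded=excluded)


@dataclass
class SignatureModel:
    """NMF decomposition of a catalog: profiles (96 x k) and exposures (k x samples).

    Profile columns are probability vectors; exposures are rescaled so
    profiles @ exposures reproduces the fitted approximation.  After
    :func:`match_to_reference`, ``similarity_to_reference`` holds the k x
    k_ref cosine matrix and ``best_match`` the argmax reference per signature.
    """

    profiles: pd.DataFrame
    exposures: pd.DataFrame
    k: int
    reconstruction_error: float
    converged: bool
    error_history: np.ndarray
    similarity_to_reference: pd.DataFrame | None = None
    best_match: dict[str, tuple[str, float]] | None = None


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    """Generalized KL divergence D(V || WH)."""
    eps = 1e-12
    WH = np.maximum(WH, eps)
    mask = V > 0
    return float((V[mask] * np.log(V[mask] / WH[mask])).sum() - V.sum() + WH.sum())


def _nmf_kl(
    V: np.ndarray, k: int, max_iter: int, tol: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """Multiplicative-update NMF under generalized KL; returns W, H, error path."""
    m, n = V.shape
    scale = np.sqrt(V.mean() / k) if V.mean() > 0 else 1.0
    W = rng.uniform(0.5, 1.5, size=(m, k)) * scale
    H = rng.uniform(0.5, 1.5, size=(k, n)) * scale
    eps = 1e-12
    errors = [_kl_divergence(V, W @ H)]
    converged = False
    for _ in range(max_iter):
        WH = np.maximum(W @ H, eps)
        H *= W.T @ (V / WH) / np.maximum(W.sum(axis=0)[:, None], eps)
        WH = np.maximum(W @ H, eps)
        W *= (V / WH) @ H.T / np.maximum(H.sum(axis=1)[None, :], eps)
        errors.append(_kl_divergence(V, W @ H))
        if errors[-2] - errors[-1] < tol * max(abs(errors[0]), 1.0):
            converged = True
            break
    return W, H, np.asarray(errors), converged


def _normalize_factors(W: np.ndarray, H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scale so each profile column of W sums to 1; W @ H is unchanged."""
    col = W.sum(axis=0)
    col[col == 0] = 1.0
    return W / col, H * col[:, None]


def _match_columns(A: np.ndarray, B: np.ndarray) -> list[int]:
    """Greedy cosine matching of B's columns onto A's; returns B-index per A column."""
    sim = cosine_similarity_matrix(A, B)
    taken: set[int] = set()
    out = [-1] * A.shape[1]
    for _ in range(A.shape[1]):
        masked = sim.copy()
        for j in taken:
            masked[:, j] = -np.inf
        for i, v in enumerate(out):
            if v >= 0:
                masked[i, :] = -np.inf
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        out[int(i)] = int(j)
        taken.add(int(j))
    return out


def extract_signatures(
    catalog: MutationCatalog,
    k: int | str = "auto",
    n_restarts: int = 10,
    max_iter: int = 500,
    seed: int = 0,
    tol: float = 1e-7,
    k_max: int = 8,
    stability_threshold: float = 0.85,
    min_relative_improvement: float = 0.02,
) -> SignatureModel:
    """Extract mutational signatures from a catalog by KL-NMF.

    The factorisation minimises generalized KL divergence with multiplicative
    updates, keeping the best of ``n_restarts`` random initialisations.  With
    ``k="auto"`` ranks 1..k_max are fitted and the chosen rank is the largest
    k whose inter-restart signature stability (mean cosine of greedily
    matched profiles against the best restart) is >= ``stability_threshold``
    and whose relative error improvement over k-1 exceeds
    ``min_relative_improvement`` (rank 1 qualifies unconditionally on the
    improvement clause).
    """
    V = catalog.matrix()
    if not V.any():
        raise ValueError("catalog is all zero; nothing to factorise")

    rng = np.random.default_rng(seed)

    norm_V = np.linalg.norm(V)

    def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
        if a.std() == 0 or b.std() == 0:
            return 1.0 if np.allclose(a, b) else 0.0
        return float(np.corrcoef(a, b)[0, 1])

    def fit_rank(r: int) -> tuple[tuple[np.ndarray, np.ndarray, np.ndarray, bool], float, float]:
        runs = [_nmf_kl(V, r, max_iter, tol, rng) for _ in range(n_restarts)]
        best = min(range(len(runs)), key=lambda i: runs[i][2][-1])
        Wb = _normalize_factors(runs[best][0], runs[best][1])[0]
        sims = []
        for i, (W, _, _, _) in enumerate(runs):
            if i == best:
                continue
            Wn = _normalize_factors(W, runs[i][1])[0]
            idx = _match_columns(Wb, Wn)
            sims.append(
                float(np.mean([_cosine(Wb[:, c], Wn[:, idx[c]]) for c in range(r)]))
            )
        stability = float(np.mean(sims)) if sims else 1.0
        Wb_raw, Hb_raw = runs[best][0], runs[best][1]
        # rank selection judges fit on the noise-floor-insensitive relative
        # Frobenius error, not the KL objective used for the updates
        fro = float(np.linalg.norm(V - Wb_raw @ Hb_raw) / max(norm_V, 1e-12))
        return runs[best], stability, fro

    def bootstrap_stability(r: int, W_full: np.ndarray, H_full: np.ndarray) -> float:
        """Refit on catalogs with each sample's mutations multinomially
        resampled; a component is stable only if both its profile and its
        exposure pattern across samples reappear.  Components that merely
        split sampling noise keep their profiles but lose the exposure
        correlation."""
        Wn_full, Hn_full = _normalize_factors(W_full.copy(), H_full.copy())
        scores = []
        for _ in range(max(3, n_restarts // 2)):
            Vb = np.empty_like(V)
            for j in range(V.shape[1]):
                total = int(V[:, j].sum())
                if total == 0:
                    Vb[:, j] = 0
                    continue
                Vb[:, j] = rng.multinomial(total, V[:, j] / V[:, j].sum())
            Wb, Hb, _, _ = _nmf_kl(Vb, r, max_iter, tol, rng)
            Wb, Hb = _normalize_factors(Wb, Hb)
            idx = _match_columns(Wn_full, Wb)
            comp_scores = []
            for c in range(r):
                prof = _cosine(Wn_full[:, c], Wb[:, idx[c]])
                expo = _safe_corr(Hn_full[c], Hb[idx[c]])
                comp_scores.append(0.5 * (prof + max(expo, 0.0)))
            scores.append(float(np.mean(comp_scores)))
        return float(np.mean(scores))

    if k == "auto":
        max_rank = min(k_max, V.shape[1])
        fits, froerrs, stabs = {}, {}, {}
        for r in range(1, max_rank + 1):
            fits[r], stabs[r], froerrs[r] = fit_rank(r)
        chosen = 1
        for r in range(2, max_rank + 1):
            improvement = (froerrs[r - 1] - froerrs[r]) / max(froerrs[r - 1], 1e-12)
            if stabs[r] < stability_threshold or improvement <= min_relative_improvement:
                continue
            if bootstrap_stability(r, fits[r][0], fits[r][1]) >= stability_threshold:
                chosen = r
        rank = chosen
        W, H, errors, converged = fits[rank]
    else:
        rank = int(k)
        if rank < 1 or rank > V.shape[1]:
            raise ValueError(f"rank {rank} outside [1, n_samples={V.shape[1]}]")
        (W, H, errors, converged), _, _ = fit_rank(rank)

    W, H = _normalize_factors(W, H)
    names = [f"S{i + 1}" for i in range(rank)]
    return SignatureModel(
        profiles=pd.DataFrame(W, index=list(CATEGORIES_96), columns=names),
        exposures=pd.DataFrame(H, index=names, columns=catalog.samples),
        k=rank,
        reconstruction_error=float(errors[-1]),
        converged=converged,
        error_history=errors,
    )


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def cosine_similarity_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity between columns of A and columns of B."""
    out = np.empty((A.shape[1], B.shape[1]))
    for i in range(A.shape[1]):
        for j in range(B.shape[1]):
            out[i, j] = _cosine(A[:, i], B[:, j])
    return out


def match_to_reference(
    model: SignatureModel, reference_catalog: pd.DataFrame
) -> tuple[SignatureModel, np.ndarray, list[str]]:
    """Match extracted signatures to a reference catalog by cosine similarity.

    The combined extracted + reference profiles are clustered with Ward
    linkage (the ward.D2 squared-dissimilarity update) on 1 - cosine
    distance.  Returns the updated model, the scipy linkage matrix, and the
    leaf labels in input order.  Argmax ties break toward the earlier
    reference column.
    """
    if list(reference_catalog.index) != list(CATEGORIES_96):
        raise ValueError("reference catalog rows must follow the fixed 96-category ordering")
    E = model.profiles.to_numpy()
    R = reference_catalog.to_numpy()
    sim = cosine_similarity_matrix(E, R)
    ref_names = list(reference_catalog.columns)
    model.similarity_to_reference = pd.DataFrame(
        sim, index=list(model.profiles.columns), columns=ref_names
    )
    model.best_match = {}
    for i, name in enumerate(model.profiles.columns):
        j = int(np.argmax(sim[i]))  # argmax returns the first maximum: earlier ref wins ties
        model.best_match[name] = (ref_names[j], float(sim[i, j]))

    combined = np.hstack([E, R])
    labels = list(model.profiles.columns) + ref_names
    n = combined.shape[1]
    dist = np.zeros((n, n))
    full = cosine_similarity_matrix(combined, combined)
    dist = np.clip(1.0 - full, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="ward")
    return model, linkage, labels


def linkage_to_newick(linkage: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(linkage)

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - (node.dist if not node.is_leaf() else 0.0), 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    # root reported with zero-length stem
    return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"


def synthetic_reference_catalog() -> pd.DataFrame:
    """A deterministic 96 x 6 catalog of synthetic but realistic profiles.

    Contains an APOBEC-like pair concentrated at TCW (T[C>T]A/T and
    T[C>G]A/T), a CpG-deamination C>T profile (N[C>T]G), an MMR-deficiency-
    like profile spread over C>T and T>C, a NER-deficiency-like broad C>A/T>A
    profile, and a flat background.  Real 96 x k catalogs (e.g. COSMIC v2)
    can be supplied instead via :func:`uromics.io.read_signature_catalog`.
    """
    idx = list(CATEGORIES_96)
    profs = pd.DataFrame(0.0, index=idx, columns=[
        "APOBEC_CT", "APOBEC_CG", "CPG_CT", "MMR_LIKE", "NER_LIKE", "FLAT",
    ])
    base = 0.1 / 96  # smoothing floor so cosines are never degenerate
    profs.loc[:, :] = base
    for three in "AT":  # TCW motif: W = A or T
        profs.loc[f"T[C>T]{three}", "APOBEC_CT"] += 0.45
        profs.loc[f"T[C>G]{three}", "APOBEC_CG"] += 0.45
    for five in "ACGT":
        profs.loc[f"{five}[C>T]G", "CPG_CT"] += 0.9 / 4
    for cat in idx:
        if "[C>T]" in cat or "[T>C]" in cat:
            profs.loc[cat, "MMR_LIKE"] += 0.9 / 32
        if "[C>A]" in cat or "[T>A]" in cat:
            profs.loc[cat, "NER_LIKE"] += 0.9 / 32
    profs.loc[:, "FLAT"] = 1.0 / 96
    return profs / profs.sum(axis=0)
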