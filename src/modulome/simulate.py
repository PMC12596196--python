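"""Synthetic expression compendia with planted co-regulation modules.

The generator emulates the statistical structure the robust-ICA
workflow assumes: a log-TPM genes × samples matrix that is the sum of a
per-gene baseline, K sparse planted modules (ground-truth gene weights
M*, heavy-tailed magnitudes, random signs) with condition-block
activities A*, and i.i.d. Gaussian noise. Samples are grouped into
replicate conditions, conditions into projects, and each project's
first condition is its reference — modules are inactive in reference
conditions, so reference-centering recovers the planted signal.

A planted TRN accompanies the matrix with four regulon classes per the
overlap geometry they produce against perfectly recovered modules:

- ``exact``     — regulon equals the module           → well-matched
- ``extended``  — regulon ⊃ module (extra targets)    → regulon subset
- ``partial``   — regulon ⊂ module (half the module)  → unknown-containing
- ``unrelated`` — background genes, no module overlap → no real enrichment

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import TRN
from .expression import ExpressionMatrix, batch_center

REGULON_CLASSES = ("exact", "extended", "partial", "unrelated")

# condition-block activity design
ACTIVITY_LEVEL = 1.0
ACTIVITY_JITTER_SD = 0.1
EXTENDED_EXTRA_FRACTION = 0.6  # extra targets per extended regulon, rel. to module size


@dataclass
class SyntheticDataset:
    """Ground-truth bundle: X = baseline + M*·A* + noise, plus TRN*."""

    X: ExpressionMatrix
    metadata: pd.DataFrame
    M_star: pd.DataFrame  # genes × modules
    A_star: pd.DataFrame  # modules × samples
    noise_sd: float
    trn_star: TRN
    seed: int

    @property
    def module_ids(self) -> list[str]:
        return list(self.M_star.columns)

    @property
    def module_members(self) -> dict[str, frozenset]:
        return {
            mid: frozenset(self.M_star.index[self.M_star[mid] != 0])
            for mid in self.module_ids
        }

    def centered(self) -> ExpressionMatrix:
        return batch_center(self.X, self.metadata)

    def signal_fraction(self) -> float:
        """Explained variance of the planted basis on the centered matrix.

        Projects centered X onto the column space of M* (activities
        refit by least squares), i.e. the explained variance an ideal
        decomposition could reach; 1.0 when noise_sd = 0.
        """
        from .ica import RobustDecomposition, explained_variance

        xc = self.centered()
        M = self.M_star.to_numpy(dtype=float)
        norms = np.linalg.norm(M, axis=0)
        norms[norms == 0] = 1.0
        decomp = RobustDecomposition(
            M=pd.DataFrame(M / norms, index=self.M_star.index, columns=self.module_ids),
            A=pd.DataFrame(np.zeros((len(self.module_ids), xc.n_samples)),
                           index=self.module_ids, columns=xc.sample_ids),
        )
        return explained_variance(xc, decomp)


def generate(
    n_genes: int = 4000,
    n_samples: int = 200,
    k_modules: int = 20,
    module_size_range: tuple[int, int] = (10, 50),
    effect_size: float = 5.0,
    noise_sd: float = 0.25,
    seed: int = 0,
    samples_per_condition: int = 2,
    reference_replicates: int = 10,
    n_projects: int = 2,
    overlap: int = 0,
) -> SyntheticDataset:
    """Generate a reproducible planted-module compendium.

    Module member sets are disjoint by default (``overlap`` > 0 lets
    adjacent modules share that many genes, stress-testing multi-module
    gene membership). Weight magnitudes are |N(effect_size,
    effect_size/5)| with random signs; module k is active at level 1 in
    a contiguous block of non-reference conditions, with N(0, 0.1)
    jitter everywhere. Each project's single reference condition
    carries ``reference_replicates`` samples (baseline conditions in
    real compendia are heavily replicated); a well-estimated reference
    mean keeps centering from re-injecting correlated noise into every
    sample of the project.
    """
    lo, hi = module_size_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid module_size_range")
    if k_modules * hi - max(0, k_modules - 1) * overlap > n_genes:
        raise ValueError("modules do not fit in the gene universe")
    if n_samples < 2 * k_modules:
        raise ValueError("need at least 2 samples per planted module")
    rng = np.random.default_rng(seed)

    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    module_ids = [f"mod_{k:02d}" for k in range(k_modules)]

    # --- conditions, projects, reference flags -------------------------------
    # Each project: one reference condition with `reference_replicates`
    # samples, then regular conditions of `samples_per_condition` samples.
    per_project = [n_samples // n_projects + (1 if p < n_samples % n_projects else 0)
                   for p in range(n_projects)]
    if min(per_project) <= reference_replicates:
        reference_replicates = max(1, min(per_project) // 3)
    cond_of_sample: list[int] = []
    proj_of_cond: list[int] = []
    ref_conditions: set[int] = set()
    for p, n_p in enumerate(per_project):
        ref_cond = len(proj_of_cond)
        proj_of_cond.append(p)
        ref_conditions.add(ref_cond)
        cond_of_sample.extend([ref_cond] * reference_replicates)
        rest = n_p - reference_replicates
        n_reg = max(1, rest // samples_per_condition)
        reg_conds = [len(proj_of_cond) + j for j in range(n_reg)]
        proj_of_cond.extend([p] * n_reg)
        for i in range(rest):
            cond_of_sample.append(reg_conds[min(i * n_reg // rest, n_reg - 1)])
    n_conditions = len(proj_of_cond)
    metadata = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "project_id": [f"proj_{proj_of_cond[c]}" for c in cond_of_sample],
            "condition": [f"cond_{c:03d}" for c in cond_of_sample],
            "is_reference": [c in ref_conditions for c in cond_of_sample],
            "replicate_group": [f"cond_{c:03d}" for c in cond_of_sample],
        }
    )

    # --- planted gene weights M* ---------------------------------------------
    sizes = rng.integers(lo, hi + 1, size=k_modules)
    perm = rng.permutation(n_genes)
    M = np.zeros((n_genes, k_modules))
    cursor = 0
    prev_members: np.ndarray | None = None
    for k in range(k_modules):
        take = int(sizes[k])
        shared = []
        if overlap and prev_members is not None:
            shared = list(prev_members[: min(overlap, len(prev_members))])
            take -= len(shared)
        fresh = perm[cursor : cursor + take]
        cursor += take
        members = np.concatenate([shared, fresh]).astype(int)
        magnitudes = np.abs(rng.normal(effect_size, effect_size / 5.0, size=len(members)))
        signs = rng.choice([-1.0, 1.0], size=len(members))
        M[members, k] = magnitudes * signs
        prev_members = members
    background_pool = perm[cursor:]  # genes in no module

    # --- condition-block activities A* ---------------------------------------
    nonref = [c for c in range(n_conditions) if c not in ref_conditions]
    if k_modules > len(nonref):
        raise ValueError("not enough non-reference conditions for the planted modules")
    block_len = max(1, len(nonref) // k_modules) if k_modules else 0
    A = np.zeros((k_modules, n_samples))
    for k in range(k_modules):
        block = set(nonref[k * block_len : (k + 1) * block_len]) or {nonref[k % len(nonref)]}
        for i, c in enumerate(cond_of_sample):
            if c in block:
                A[k, i] = ACTIVITY_LEVEL
    A = A + rng.normal(0.0, ACTIVITY_JITTER_SD, size=A.shape)

    # --- assemble X ≥ 0 -------------------------------------------------------
    baseline = rng.uniform(0.5, 3.5, size=n_genes)
    noise = rng.normal(0.0, noise_sd, size=(n_genes, n_samples)) if noise_sd > 0 else 0.0
    raw = baseline[:, None] + M @ A + noise
    shift = max(0.0, -float(np.min(raw)))  # per-gene constants vanish under centering
    X = ExpressionMatrix(pd.DataFrame(raw + shift, index=gene_ids, columns=sample_ids))

    trn_star = _planted_trn(rng, M, gene_ids, module_ids, background_pool, k_modules)
    return SyntheticDataset(
        X=X,
        metadata=metadata,
        M_star=pd.DataFrame(M, index=gene_ids, columns=module_ids),
        A_star=pd.DataFrame(A, index=module_ids, columns=sample_ids),
        noise_sd=noise_sd,
        trn_star=trn_star,
        seed=seed,
    )


def _planted_trn(rng, M, gene_ids, module_ids, background_pool, k_modules) -> TRN:
    """Planted TRN: one class-labeled regulon per module + unrelated extras."""
    rows = []
    bg_cursor = 0
    for k in range(k_modules):
        members = [gene_ids[i] for i in np.flatnonzero(M[:, k])]
        cls = REGULON_CLASSES[k % 3]  # exact / extended / partial, round-robin
        regulator = f"Reg_{cls}_{module_ids[k]}"
        if cls == "exact":
            targets = members
        elif cls == "extended":
            n_extra = int(np.ceil(EXTENDED_EXTRA_FRACTION * len(members)))
            extras = [gene_ids[i] for i in background_pool[bg_cursor : bg_cursor + n_extra]]
            bg_cursor += n_extra
            targets = members + extras
        else:  # partial: half the module
            targets = members[: max(1, len(members) // 2)]
        rows.extend((regulator, t, cls) for t in targets)
    n_unrelated = max(1, k_modules // 4)
    for j in range(n_unrelated):
        size = int(rng.integers(5, 15))
        targets = [gene_ids[i] for i in background_pool[bg_cursor : bg_cursor + size]]
        bg_cursor += size
        rows.extend((f"Reg_unrelated_{j:02d}", t, "unrelated") for t in targets)
    table = pd.DataFrame(rows, columns=["regulator", "target", "evidence"])
    return TRN(associations=table, gene_universe=frozenset(gene_ids))


@dataclass
class MatchResult:
    matched_fraction: float
    best_abs_corr: pd.Series  # per planted module
    membership_f1: pd.Series  # per planted module (0 where unmatched)
    assignment: dict  # planted module id -> recovered component id


def match_components(
    M_recovered: pd.DataFrame,
    M_star: pd.DataFrame,
    min_abs_corr: float = 0.8,
    k2_cutoff: float | None = None,
) -> MatchResult:
    """Greedy one-to-one matching of recovered components to planted modules.

    Pairs are matched in order of descending |Pearson ρ| between weight
    columns until the correlation drops below ``min_abs_corr``.
    Membership F1 compares each matched component's thresholded member
    set against the planted (nonzero-weight) member set; unmatched
    modules score 0.
    """
    from .membership import DEFAULT_K2_CUTOFF, members_f1, threshold_component

    if list(M_recovered.index) != list(M_star.index):
        raise ValueError("gene order mismatch between recovered and planted weights")
    if k2_cutoff is None:
        k2_cutoff = DEFAULT_K2_CUTOFF
    k_star = M_star.shape[1]
    module_ids = list(M_star.columns)
    if M_recovered.shape[1] == 0 or k_star == 0:
        zeros = pd.Series(0.0, index=module_ids)
        return MatchResult(0.0, zeros, zeros.copy(), {})

    R = M_recovered.to_numpy()
    S = M_star.to_numpy()
    Rz = (R - R.mean(0)) / R.std(0)
    Sz = (S - S.mean(0)) / S.std(0)
    C = np.abs(Rz.T @ Sz) / R.shape[0]  # |corr|, recovered × planted

    best = pd.Series(C.max(axis=0), index=module_ids)
    assignment: dict[str, str] = {}
    C_work = C.copy()
    while True:
        i, j = np.unravel_index(np.argmax(C_work), C_work.shape)
        if C_work[i, j] < min_abs_corr:
            break
        assignment[module_ids[j]] = M_recovered.columns[i]
        C_work[i, :] = -1.0
        C_work[:, j] = -1.0
        if len(assignment) == min(C.shape):
            break

    f1 = {}
    true_members = {mid: set(M_star.index[M_star[mid] != 0]) for mid in module_ids}
    for mid in module_ids:
        if mid not in assignment:
            f1[mid] = 0.0
            continue
        res = threshold_component(M_recovered[assignment[mid]], k2_cutoff)
        f1[mid] = members_f1(res.members, true_members[mid]) if res.members else 0.0
    return MatchResult(
        matched_fraction=len(assignment) / k_star,
        best_abs_corr=best,
        membership_f1=pd.Series(f1).loc[module_ids],
        assignment=assignment,
    )


def write_dataset(ds: SyntheticDataset, out_dir) -> None:
    """Write the dataset in the same formats the pipeline reads,
    alongside ground truth and a manifest."""
    os.makedirs(out_dir, exist_ok=True)
    ds.X.data.to_csv(os.path.join(out_dir, "expression.tsv"), sep="\t")
    ds.metadata.to_csv(os.path.join(out_dir, "metadata.csv"), index=False)
    ds.trn_star.to_csv(os.path.join(out_dir, "trn.csv"))
    ds.M_star.to_csv(os.path.join(out_dir, "M_star.tsv"), sep="\t")
    ds.A_star.to_csv(os.path.join(out_dir, "A_star.tsv"), sep="\t")
    manifest = {
        "seed": ds.seed,
        "noise_sd": ds.noise_sd,
        "n_genes": ds.X.n_genes,
        "n_samples": ds.X.n_samples,
        "k_modules": len(ds.module_ids),
    }
    with open(os.path.join(out_dir, "dataset_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
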