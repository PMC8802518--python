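"""The quantification engine: EM over equivalence classes with iterative,
mass-preserving set-cover thresholding.

The generative model treats each sequenced fragment as drawn by first
selecting a reference strain r_i with prior probability Pr(r_i | θ) and then
emitting a fragment compatible with it; over (range-factorized) equivalence
classes the log-likelihood is

    ℓ(θ) = Σ_q N^q · log Σ_{i ∈ Ω(q)} Pr(r_i | θ) · Pr(f | F^q, r_i)

Expectation-maximization alternates computing per-class responsibilities
(E) with reassigning class counts to references and renormalizing the
mixture (M). Plain EM cannot break the symmetry of *multi-mapping islands*
— groups of near-identical, low-abundance references whose every fragment
is ambiguous within the group — so every ``k_between_setcover`` iterations
a four-step thresholding round runs:

1. mark references with estimated count ≤ cutoff as potentially removable
   (PR);
2. safely remove PR references whose every class retains a non-PR member;
3. for the rest, greedily solve the set-cover problem over *critical*
   classes (classes whose members are all PR), retaining a small set of PR
   references that explains every critical class;
4. update class labels/weights, merging classes that become identical.

No fragment is ever discarded by thresholding: removed references' mass is
redistributed by the next EM step. Once a round removes nothing, EM runs to
convergence and a final abundance cutoff (default: drop ≤ 2 fragments)
produces the report.

The module exposes both the statsmodels-style :class:`CedarModel` /
:class:`CedarResults` pair and the individual algorithm steps as functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .eqclass import ClassCollection, EquivalenceClass
from .references import ReferenceSet

#: responsibilities above this take part in coverage-ratio computation
COVERAGE_RESP_MIN = 0.01
#: floor for coverage ratios so no active reference gets a hard-zero prior
COVERAGE_FLOOR = 1e-6


@dataclass(frozen=True)
class QuantOptions:
    """Engine options.

    k_between_setcover
        EM iterations between thresholding rounds (fragments are never lost
        in a round).
    max_iterations
        Total EM iteration budget.
    convergence_tol
        Maximum absolute change of any reference's estimated count, in
        fragments, below which the final EM phase stops.
    cutoff
        Abundance cutoff in fragments; used both for PR marking and the
        final removal.
    cutoff_inclusive
        Drop references with count ≤ cutoff (the worked-example reading);
        ``False`` drops strictly-below only.
    use_coverage_prior
        Multiply the prior by each reference's coverage ratio (fraction of
        effective-length positions covered by confidently assigned
        fragments, recomputed once per thresholding round).
    """

    k_between_setcover: int = 10
    max_iterations: int = 1000
    convergence_tol: float = 0.01
    cutoff: float = 2.0
    cutoff_inclusive: bool = True
    use_coverage_prior: bool = True

    def __post_init__(self) -> None:
        if self.k_between_setcover < 1:
            raise ValueError("k_between_setcover must be >= 1")
        if self.cutoff < 0:
            raise ValueError("cutoff must be >= 0")


@dataclass
class AbundanceState:
    """Current mixture parameters and estimated counts.

    ``theta``/``est_reads``/``coverage_ratio`` are dense over all references
    in the collection's reference set; inactive references hold zeros.
    """

    theta: np.ndarray
    est_reads: np.ndarray
    active: set[int]
    coverage_ratio: np.ndarray
    iteration: int = 0

    @classmethod
    def uniform(cls, collection: ClassCollection) -> "AbundanceState":
        m = len(collection.refs)
        active = collection.active_refs()
        theta = np.zeros(m)
        if active:
            idx = np.fromiter(active, dtype=np.int64)
            theta[idx] = 1.0 / len(active)
        total = collection.total_fragments
        est = np.zeros(m)
        if active:
            est[idx] = total / len(active)
        return cls(theta=theta, est_reads=est, active=active, coverage_ratio=np.ones(m))


def _responsibilities(
    state: AbundanceState, collection: ClassCollection, use_coverage: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-label-entry responsibilities, normalized within each class.

    Returns (flat responsibilities, flat ref indices, class counts).
    """
    ref_idx, ptr, counts, weights = collection.flat()
    prior = state.theta * (state.coverage_ratio if use_coverage else 1.0)
    vals = prior[ref_idx] * weights
    seg = np.add.reduceat(vals, ptr) if len(ptr) else np.array([])
    sizes = np.diff(np.append(ptr, len(ref_idx)))
    # a class whose priors all vanished falls back to its weights alone
    bad = seg <= 0.0
    if np.any(bad):
        bad_flat = np.repeat(bad, sizes)
        vals = np.where(bad_flat, weights, vals)
        seg = np.add.reduceat(vals, ptr)
    resp = vals / np.repeat(seg, sizes)
    return resp, ref_idx, counts


def em_iteration(
    state: AbundanceState, collection: ClassCollection, use_coverage: bool = True
) -> AbundanceState:
    """One E+M step.

    E: responsibility of reference i for class q ∝ prior_i · weight_{q,i},
    normalized within the class, with prior_i = θ_i (times the coverage
    ratio when enabled). M: est_reads_i = Σ_q N^q · responsibility; θ ∝
    est_reads / effective_length, normalized. Total estimated reads equal
    the total fragment count by construction.
    """
    m = len(collection.refs)
    resp, ref_idx, counts = _responsibilities(state, collection, use_coverage)
    sizes = np.array([len(c.label) for c in collection.classes], dtype=np.int64)
    frag = resp * np.repeat(counts, sizes)
    est = np.bincount(ref_idx, weights=frag, minlength=m)
    eff = collection.refs.effective_lengths
    theta = est / eff
    total_theta = theta.sum()
    if total_theta > 0:
        theta = theta / total_theta
    return AbundanceState(
        theta=theta,
        est_reads=est,
        active=state.active,
        coverage_ratio=state.coverage_ratio,
        iteration=state.iteration + 1,
    )


def log_likelihood(
    state: AbundanceState, collection: ClassCollection, use_coverage: bool = True
) -> float:
    """Range-factorized log-likelihood at the current estimates.

    Evaluated in read-fraction coordinates π_i = est_i / total with
    per-class conditionals w_{q,i} · coverage_i / effective_length_i — the
    parameterization in which the engine's E/M updates are exactly classical
    EM, so this quantity is non-decreasing across iterations between
    thresholding rounds.
    """
    ref_idx, ptr, counts, weights = collection.flat()
    total = counts.sum()
    if total == 0:
        return 0.0
    pi = state.est_reads / total
    cov = state.coverage_ratio if use_coverage else np.ones_like(pi)
    v = weights * (pi * cov / collection.refs.effective_lengths)[ref_idx]
    seg = np.add.reduceat(v, ptr)
    seg = np.maximum(seg, 1e-300)
    return float(np.dot(counts, np.log(seg)))


def compute_coverage_ratios(
    state: AbundanceState, collection: ClassCollection
) -> np.ndarray:
    """Fraction of each reference's effective length covered by fragments
    currently assigned with responsibility > 0.01 (distinct start
    positions / effective length, clipped to [COVERAGE_FLOOR, 1]).

    References without positional information (classes loaded from a text
    table) keep ratio 1.
    """
    m = len(collection.refs)
    resp, ref_idx, _ = _responsibilities(state, collection, use_coverage=True)
    pos_sets: dict[int, set[int]] = {}
    has_positions = False
    flat_pos = 0
    for c in collection.classes:
        for j, i in enumerate(c.label):
            if resp[flat_pos + j] > COVERAGE_RESP_MIN and i in c.positions:
                has_positions = True
                pos_sets.setdefault(i, set()).update(c.positions[i].tolist())
        flat_pos += len(c.label)
    cov = np.ones(m)
    if not has_positions:
        return cov
    eff = collection.refs.effective_lengths
    for i in state.active:
        n = len(pos_sets.get(i, ()))
        cov[i] = min(1.0, max(COVERAGE_FLOOR, n / eff[i]))
    return cov


# ---------------------------------------------------------------------------
# the four thresholding steps


def mark_potentially_removable(state: AbundanceState, cutoff: float) -> set[int]:
    """Step 1: active references with estimated count ≤ cutoff."""
    return {i for i in state.active if state.est_reads[i] <= cutoff}


def remove_safe_pr(pr: set[int], collection: ClassCollection) -> set[int]:
    """Step 2: PR references whose every class retains a non-PR member.

    Removing these cannot orphan any class, hence cannot lose any read.
    """
    unsafe: set[int] = set()
    for c in collection.classes:
        if all(i in pr for i in c.label):
            unsafe.update(c.label)
    return pr - unsafe


def critical_classes(
    collection: ClassCollection, pr: set[int]
) -> list[EquivalenceClass]:
    """Classes whose every labeled reference is potentially removable."""
    return [c for c in collection.classes if all(i in pr for i in c.label)]


def greedy_set_cover(
    critical: Sequence[EquivalenceClass],
    candidates: set[int],
    state: AbundanceState,
    ref_ids: Sequence[str] | None = None,
) -> set[int]:
    """Step 3: greedily retain PR references covering all critical classes.

    Repeatedly pick the candidate covering the most still-uncovered critical
    classes; ties prefer higher current estimated count, then the
    lexicographically smaller reference id. Returns the retained set; the
    remaining candidates can be removed without losing any fragment.
    """
    if not critical:
        return set()
    uncovered = set(range(len(critical)))
    covers: dict[int, set[int]] = {i: set() for i in candidates}
    for qi, c in enumerate(critical):
        for i in c.label:
            if i not in covers:
                raise ValueError(
                    f"critical class member {i} is not among the candidates"
                )
            covers[i].add(qi)
    retained: set[int] = set()
    while uncovered:
        def rank(i: int):
            name = ref_ids[i] if ref_ids is not None else str(i)
            return (-len(covers[i] & uncovered), -state.est_reads[i], name)

        pick = min(candidates - retained, key=rank)
        gain = covers[pick] & uncovered
        if not gain:
            raise AssertionError("uncoverable critical class")  # impossible by construction
        retained.add(pick)
        uncovered -= gain
    return retained


def update_classes(
    collection: ClassCollection, removed: set[int]
) -> ClassCollection:
    """Step 4: delete removed references from labels, renormalize surviving
    weights (so the best surviving reference keeps weight 1), and merge
    classes whose (label, bin signature) became identical, summing counts.

    The total fragment count is unchanged; emptying a class is a hard error
    (it would mean steps 2–3 violated their contract).
    """
    if not removed:
        return collection
    acc: dict[tuple[tuple[int, ...], tuple[int, ...]], list] = {}
    for c in collection.classes:
        keep = [j for j, i in enumerate(c.label) if i not in removed]
        if not keep:
            raise AssertionError(
                f"class {c.label} emptied by removal — thresholding bug"
            )
        if len(keep) == len(c.label):
            label, sig, weights = c.label, c.bin_signature, c.weights
            positions = c.positions
        else:
            label = tuple(c.label[j] for j in keep)
            sig = tuple(c.bin_signature[j] for j in keep) if c.bin_signature else ()
            weights = c.weights[keep]
            weights = weights / weights.max()
            positions = {i: p for i, p in c.positions.items() if i in label}
        key = (label, sig)
        slot = acc.get(key)
        if slot is None:
            acc[key] = [c.count, weights * c.count, dict(positions)]
        else:
            slot[0] += c.count
            slot[1] = slot[1] + weights * c.count
            for i, p in positions.items():
                old = slot[2].get(i)
                slot[2][i] = p if old is None else np.union1d(old, p)
    classes = [
        EquivalenceClass(
            label=label, count=n, weights=wsum / n, bin_signature=sig, positions=posd
        )
        for (label, sig), (n, wsum, posd) in sorted(acc.items())
    ]
    return ClassCollection(
        classes=classes, refs=collection.refs, unmapped=collection.unmapped
    )


# ---------------------------------------------------------------------------
# driver


@dataclass
class FitTrace:
    """Per-iteration diagnostics recorded while fitting.

    ``mass`` and ``loglik`` have one entry per EM iteration; ``stretch`` tags
    the thresholding round each iteration belongs to (log-likelihood is
    monotone within a stretch, not across them). ``round_mass`` records the
    total estimated count after each thresholding round.
    """

    mass: list[float] = field(default_factory=list)
    loglik: list[float] = field(default_factory=list)
    stretch: list[int] = field(default_factory=list)
    round_mass: list[float] = field(default_factory=list)
    n_rounds: int = 0


class CedarModel:
    """Abundance model over a collection of equivalence classes.

    Parameters
    ----------
    collection
        Equivalence classes with their reference view (build with
        :func:`cedarquant.eqclass.build_classes`, load with
        :func:`cedarquant.eqclass.read_class_table`, or derive from SAM via
        :meth:`from_sam`).
    options
        Engine options; defaults follow the method's published defaults
        (k = 10 EM iterations per step, 1000 iterations maximum, cutoff 2).
    """

    def __init__(self, collection: ClassCollection, options: QuantOptions | None = None):
        if not collection.classes:
            raise ValueError("empty class collection")
        self.collection = collection
        self.options = options or QuantOptions()

    @classmethod
    def from_sam(
        cls,
        sam_path,
        refs: ReferenceSet | None = None,
        bins: int = 4,
        alpha: float = 1.0,
        scheme=None,
        options: QuantOptions | None = None,
    ) -> "CedarModel":
        """Build the model from a SAM file carrying AS:i: score tags.

        Records are score-filtered per fragment before class construction.
        When ``refs`` is omitted, lengths are taken from the SAM header.
        """
        import pysam

        from .eqclass import build_classes
        from .mapper import ScoringScheme, filter_by_score
        from .samio import read_sam_fragments

        scheme = scheme or ScoringScheme()
        if refs is None:
            with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as fh:
                refs = ReferenceSet(
                    ids=list(fh.references),
                    lengths=np.array(fh.lengths, dtype=np.int64),
                )

        def filtered():
            for frag_id, records in read_sam_fragments(sam_path):
                # fragment length proxy: matched+inserted bases of the best record
                yield frag_id, records

        collection = build_classes(filtered(), refs, bins=bins, alpha=alpha)
        return cls(collection, options)

    @classmethod
    def from_class_table(cls, path, options: QuantOptions | None = None) -> "CedarModel":
        from .eqclass import read_class_table

        return cls(read_class_table(path), options)

    def fit(
        self,
        trace: bool = False,
        callback: Callable[[AbundanceState, ClassCollection], None] | None = None,
    ) -> "CedarResults":
        """Run the EM / set-cover loop to completion and report.

        The loop runs ``k_between_setcover`` EM iterations, then a
        thresholding round; once a round removes nothing, EM continues to
        convergence (max absolute change in estimated counts ≤
        ``convergence_tol``) or the iteration budget, and the final cutoff
        is applied. Mass is preserved through every round; only the final
        cutoff discards (logged) mass.
        """
        opts = self.options
        collection = self.collection
        total = collection.total_fragments
        state = AbundanceState.uniform(collection)
        tr = FitTrace()
        removal_log: list[tuple[str, str, int]] = []
        n_refs_initial = len(state.active)
        round_idx = 0
        stretch = 0
        use_cov = opts.use_coverage_prior

        def run_em(n: int, until_converged: bool) -> None:
            nonlocal state
            prev = state.est_reads
            for _ in range(n):
                if state.iteration >= opts.max_iterations:
                    return
                state = em_iteration(state, collection, use_cov)
                if trace:
                    tr.mass.append(float(state.est_reads.sum()))
                    tr.loglik.append(log_likelihood(state, collection, use_cov))
                    tr.stretch.append(stretch)
                if callback is not None:
                    callback(state, collection)
                if until_converged and np.max(np.abs(state.est_reads - prev)) <= opts.convergence_tol:
                    return
                prev = state.est_reads

        while True:
            run_em(opts.k_between_setcover, until_converged=False)
            if state.iteration >= opts.max_iterations:
                break

            # thresholding round (steps 1-4)
            pr = mark_potentially_removable(state, opts.cutoff)
            safe = remove_safe_pr(pr, collection)
            removed_this_round: set[int] = set(safe)
            for i in sorted(safe):
                removal_log.append((collection.refs.ids[i], "safe-PR", round_idx))
            if safe:
                collection = update_classes(collection, safe)
            unsafe = pr - safe
            if unsafe:
                critical = critical_classes(collection, unsafe)
                retained = greedy_set_cover(
                    critical, unsafe, state, ref_ids=collection.refs.ids
                )
                dropped = unsafe - retained
                for i in sorted(dropped):
                    removal_log.append((collection.refs.ids[i], "set-cover", round_idx))
                if dropped:
                    collection = update_classes(collection, dropped)
                removed_this_round |= dropped

            if removed_this_round:
                state.active -= removed_this_round
                theta = state.theta.copy()
                theta[list(removed_this_round)] = 0.0
                s = theta.sum()
                state = AbundanceState(
                    theta=theta / s if s > 0 else theta,
                    est_reads=state.est_reads,
                    active=state.active,
                    coverage_ratio=state.coverage_ratio,
                    iteration=state.iteration,
                )
                # one E/M pass reassigns the removed references' fragments so
                # the round itself preserves total mass
                stretch += 1
                if use_cov:
                    state.coverage_ratio = compute_coverage_ratios(state, collection)
                state = em_iteration(state, collection, use_cov)
                if trace:
                    tr.mass.append(float(state.est_reads.sum()))
                    tr.loglik.append(log_likelihood(state, collection, use_cov))
                    tr.stretch.append(stretch)
                if callback is not None:
                    callback(state, collection)
                if trace:
                    tr.round_mass.append(float(state.est_reads.sum()))
                round_idx += 1
                if round_idx > n_refs_initial:
                    raise AssertionError(
                        "thresholding rounds exceeded the reference count — "
                        "termination bound violated"
                    )
            else:
                if trace:
                    tr.round_mass.append(float(state.est_reads.sum()))
                break

        # final EM phase to convergence
        stretch += 1
        if use_cov:
            state.coverage_ratio = compute_coverage_ratios(state, collection)
        run_em(opts.max_iterations - state.iteration, until_converged=True)
        tr.n_rounds = round_idx

        # final cutoff
        reported: dict[str, float] = {}
        discarded_mass = 0.0
        for i in sorted(state.active):
            est = float(state.est_reads[i])
            below = est <= opts.cutoff if opts.cutoff_inclusive else est < opts.cutoff
            if below:
                removal_log.append((collection.refs.ids[i], "final-cutoff", round_idx))
                discarded_mass += est
            else:
                reported[collection.refs.ids[i]] = est

        return CedarResults(
            model=self,
            final_collection=collection,
            state=state,
            est_reads=reported,
            removal_log=removal_log,
            total_fragments=total,
            discarded_mass=discarded_mass,
            trace=tr if trace else None,
        )


class CedarResults:
    """Fitted abundances plus removal diagnostics.

    Attributes
    ----------
    est_reads
        reference id → estimated fragment count, reported references only.
    removal_log
        (reference id, reason ∈ {safe-PR, set-cover, final-cutoff}, round).
    discarded_mass
        Fragments attributed to references dropped by the final cutoff (the
        only step that discards mass).
    """

    def __init__(
        self,
        model: CedarModel,
        final_collection: ClassCollection,
        state: AbundanceState,
        est_reads: dict[str, float],
        removal_log: list[tuple[str, str, int]],
        total_fragments: int,
        discarded_mass: float,
        trace: FitTrace | None,
    ):
        self.model = model
        self.final_collection = final_collection
        self.state = state
        self.est_reads = est_reads
        self.removal_log = removal_log
        self.total_fragments = total_fragments
        self.discarded_mass = discarded_mass
        self.trace = trace

    @property
    def n_iterations(self) -> int:
        return self.state.iteration

    def removal_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.removal_log, columns=["reference_id", "reason", "round"])

    def frame(self) -> pd.DataFrame:
        """Raw quantification table.

        Columns: reference_id, taxid, length, effective_length,
        estimated_reads, read_fraction (of all mapped fragments) and
        nucleotide_fraction (effective-length-normalized read fraction).
        """
        refs = self.model.collection.refs
        eff = refs.effective_lengths
        rows = []
        for rid, est in self.est_reads.items():
            i = refs.index_of(rid)
            rows.append(
                {
                    "reference_id": rid,
                    "taxid": int(refs.taxids[i]),
                    "length": int(refs.lengths[i]),
                    "effective_length": float(eff[i]),
                    "estimated_reads": est,
                    "read_fraction": est / self.total_fragments if self.total_fragments else 0.0,
                }
            )
        df = pd.DataFrame(
            rows,
            columns=[
                "reference_id", "taxid", "length", "effective_length",
                "estimated_reads", "read_fraction",
            ],
        )
        if len(df):
            nuc = df["estimated_reads"] / df["effective_length"]
            df["nucleotide_fraction"] = nuc / nuc.sum()
        else:
            df["nucleotide_fraction"] = pd.Series(dtype=float)
        return df.sort_values("estimated_reads", ascending=False, ignore_index=True)

    def summary(self) -> str:
        df = self.frame()
        lines = [
            "Cedar quantification summary",
            "=" * 64,
            f"total mapped fragments     {self.total_fragments}",
            f"EM iterations              {self.n_iterations}",
            f"thresholding rounds        {self.trace.n_rounds if self.trace else 'n/a'}",
            f"references reported        {len(df)}",
            f"references removed         {len(self.removal_log)}",
            f"mass discarded by cutoff   {self.discarded_mass:.3f}",
            "-" * 64,
            df.to_string(
                index=False,
                float_format=lambda x: f"{x:.4f}",
                max_rows=40,
            ),
        ]
        if self.removal_log:
            lines.append("-" * 64)
            lines.append("removals (reference, reason, round):")
            for rid, reason, rnd in self.removal_log[:40]:
                lines.append(f"  {rid:<24s} {reason:<12s} {rnd}")
        return "\n".join(lines)

    def to_tsv(self, path, header_comment: str | None = None) -> None:
        df = self.frame()
        with open(path, "w") as fh:
            if header_comment:
                for line in header_comment.splitlines():
                    fh.write(f"# {line}\n")
            df.to_csv(fh, sep="\t", index=False)


def quantify(
    collection: ClassCollection,
    options: QuantOptions | None = None,
    trace: bool = False,
) -> CedarResults:
    """Functional entry point: fit a :class:`CedarModel` on the collection."""
    return CedarModel(collection, options).fit(trace=trace)
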