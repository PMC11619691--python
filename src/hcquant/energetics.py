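"""Binding energetics: trajectory statistics and alchemical free energies.

Two halves:

* Trajectory statistics — residue contact fractions (fraction of frames
  where the minimum heavy-atom distance between two selections is below a
  cutoff, default 3 A) and RMSD series with optional Kabsch superposition.
  Trajectories arrive as multi-model PDB or in-memory coordinate arrays;
  the package never runs molecular dynamics itself.

* Free-energy post-processing — per-lambda-window forward/reverse work
  samples are combined with the Bennett acceptance ratio (BAR, the
  minimum-variance two-sided estimator) or the one-sided exponential
  averaging estimator; windows sum into a leg (complex or free), legs
  combine through the thermodynamic cycle ddG = dG_complex - dG_free, and
  per-protomer ddG values of the hexameric hemichannel sum into a total
  that converts to a binding-affinity fold change exp(ddG/RT).

Sign convention: the alchemical transformation runs wild-type -> mutant,
so a positive ddG means the mutation weakens antibody binding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.spatial.distance import cdist
from scipy.special import expit, logsumexp

from ._util import kt

__all__ = [
    "TrajectoryFrames", "ContactResult", "WindowWorkSamples",
    "FreeEnergyLeg", "ProtomerContributions",
    "contact_fraction", "rmsd_series", "exp_estimator", "bar_estimator",
    "combine_leg", "thermo_cycle", "aggregate_protomers", "fold_change",
]


# ---------------------------------------------------------------------------
# Trajectory containers and statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrajectoryFrames:
    """A fixed atom roster with coordinates for every frame.

    ``atoms`` is a DataFrame with columns chain, res_number, res_name,
    atom_name, is_hydrogen; ``coords`` has shape (n_frames, n_atoms, 3) in
    Angstrom.
    """

    atoms: pd.DataFrame
    coords: np.ndarray

    def __post_init__(self):
        required = {"chain", "res_number", "res_name", "atom_name",
                    "is_hydrogen"}
        if not required.issubset(self.atoms.columns):
            raise ValueError(f"atoms table must have columns {sorted(required)}")
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 3 or c.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if c.shape[1] != len(self.atoms):
            raise ValueError("coords second axis must match the atom roster")
        if not np.all(np.isfinite(c)):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "coords", c)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def select(self, chain: str | None = None,
               res_number: int | None = None,
               heavy_only: bool = True) -> np.ndarray:
        """Boolean atom mask for a chain/residue selection."""
        m = np.ones(len(self.atoms), dtype=bool)
        if chain is not None:
            m &= (self.atoms["chain"] == chain).to_numpy()
        if res_number is not None:
            m &= (self.atoms["res_number"] == res_number).to_numpy()
        if heavy_only:
            m &= ~self.atoms["is_hydrogen"].to_numpy()
        return m

    # -- multi-model PDB I/O (via biotite) ---------------------------------

    def to_pdb(self, path) -> None:
        import biotite.structure as struc
        from biotite.structure.io.pdb import PDBFile

        n = len(self.atoms)
        stack = struc.AtomArrayStack(self.n_frames, n)
        stack.coord = self.coords.astype(np.float32)
        stack.chain_id = self.atoms["chain"].to_numpy(dtype="U4")
        stack.res_id = self.atoms["res_number"].to_numpy(dtype=int)
        stack.res_name = self.atoms["res_name"].to_numpy(dtype="U5")
        stack.atom_name = self.atoms["atom_name"].to_numpy(dtype="U6")
        stack.element = np.where(self.atoms["is_hydrogen"], "H", "C")
        pdb = PDBFile()
        pdb.set_structure(stack)
        pdb.write(str(path))

    @classmethod
    def from_pdb(cls, path) -> "TrajectoryFrames":
        from biotite.structure.io.pdb import PDBFile

        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None)
        atoms = pd.DataFrame({
            "chain": stack.chain_id,
            "res_number": stack.res_id,
            "res_name": stack.res_name,
            "atom_name": stack.atom_name,
            "is_hydrogen": np.char.strip(stack.element.astype(str)) == "H",
        })
        return cls(atoms=atoms, coords=np.asarray(stack.coord, dtype=float))


@dataclass(frozen=True)
class ContactResult:
    """Fraction of frames with inter-selection contact below the cutoff."""

    selection_a: dict
    selection_b: dict
    cutoff: float
    fraction: float
    per_frame: np.ndarray

    def __post_init__(self):
        f = float(np.mean(self.per_frame)) if len(self.per_frame) else 0.0
        if abs(f - self.fraction) > 1e-12:
            raise ValueError("fraction must equal mean(per_frame)")


def _resolve_selection(traj: TrajectoryFrames, sel) -> np.ndarray:
    if isinstance(sel, dict):
        return traj.select(**sel)
    mask = np.asarray(sel, dtype=bool)
    if mask.shape != (len(traj.atoms),):
        raise ValueError("selection mask length must match the atom roster")
    # contacts are defined on heavy atoms only
    return mask & ~traj.atoms["is_hydrogen"].to_numpy()


def contact_fraction(traj: TrajectoryFrames, sel_a, sel_b,
                     cutoff: float = 3.0) -> ContactResult:
    """Per-frame minimum heavy-atom distance thresholded at the cutoff.

    A frame counts as contact iff the minimum distance between the two
    selections is strictly below ``cutoff`` (a pair at exactly the cutoff is
    a non-contact). Hydrogens are excluded from both selections.
    """
    ma = _resolve_selection(traj, sel_a)
    mb = _resolve_selection(traj, sel_b)
    if not ma.any() or not mb.any():
        raise ValueError("selections must be non-empty (after removing H)")
    if np.any(ma & mb):
        raise ValueError("selections must be disjoint")
    per_frame = np.empty(traj.n_frames, dtype=bool)
    for f in range(traj.n_frames):
        d = cdist(traj.coords[f, ma], traj.coords[f, mb])
        per_frame[f] = bool(d.min() < cutoff)
    sa = sel_a if isinstance(sel_a, dict) else {"mask": "custom"}
    sb = sel_b if isinstance(sel_b, dict) else {"mask": "custom"}
    return ContactResult(selection_a=sa, selection_b=sb, cutoff=cutoff,
                         fraction=float(per_frame.mean()),
                         per_frame=per_frame)


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal rigid-body superposition of ``mobile`` onto ``reference``."""
    mc = mobile - mobile.mean(axis=0)
    rc = reference - reference.mean(axis=0)
    h = mc.T @ rc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    return mc @ rot + reference.mean(axis=0)


def rmsd_series(traj: TrajectoryFrames, reference: int = 0,
                align: bool = True,
                atom_mask: np.ndarray | None = None) -> np.ndarray:
    """RMSD of every frame to a reference frame, in Angstrom.

    With ``align=True`` each frame is first superposed onto the reference by
    the Kabsch algorithm, so the series is invariant to rigid-body motion.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    if atom_mask is None:
        atom_mask = np.ones(len(traj.atoms), dtype=bool)
    ref = traj.coords[reference, atom_mask]
    if align and ref.shape[0] < 3:
        raise ValueError("alignment needs at least 3 atoms")
    if align:
        # collinear atom sets leave a rotational degree of freedom
        centered = ref - ref.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
            raise ValueError("alignment needs non-collinear atoms")
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        xyz = traj.coords[f, atom_mask]
        if align:
            xyz = kabsch_superpose(xyz, ref)
        out[f] = np.sqrt(np.mean(np.sum((xyz - ref) ** 2, axis=1)))
    return out


# ---------------------------------------------------------------------------
# Free-energy estimation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WindowWorkSamples:
    """Forward/reverse work samples (kcal/mol) of the lambda windows."""

    forward: list  # list of arrays, one per window
    reverse: list
    temperature: float  # K

    def __post_init__(self):
        if len(self.forward) != len(self.reverse):
            raise ValueError("forward and reverse must have one list per window")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        fw = [np.asarray(w, dtype=float) for w in self.forward]
        rv = [np.asarray(w, dtype=float) for w in self.reverse]
        for w in fw + rv:
            if w.size < 2:
                raise ValueError("each window direction needs >= 2 samples")
        object.__setattr__(self, "forward", fw)
        object.__setattr__(self, "reverse", rv)

    @property
    def n_windows(self) -> int:
        return len(self.forward)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, (f, r) in enumerate(zip(self.forward, self.reverse)):
            for w in f:
                rows.append((i, "forward", w, self.temperature))
            for w in r:
                rows.append((i, "reverse", w, self.temperature))
        return pd.DataFrame(rows, columns=["window", "direction",
                                           "work_kcal_mol", "temperature_k"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "WindowWorkSamples":
        temp = float(df["temperature_k"].iloc[0])
        fwd, rev = [], []
        for _, grp in df.groupby("window", sort=True):
            fwd.append(grp.loc[grp["direction"] == "forward",
                               "work_kcal_mol"].to_numpy())
            rev.append(grp.loc[grp["direction"] == "reverse",
                               "work_kcal_mol"].to_numpy())
        return cls(forward=fwd, reverse=rev, temperature=temp)


@dataclass(frozen=True)
class FreeEnergyLeg:
    """One leg of the thermodynamic cycle (complex or free)."""

    label: str  # "complex" or "free"
    dg: float   # kcal/mol
    se: float
    per_window: list  # list of (dg_i, se_i)


@dataclass(frozen=True)
class ProtomerContributions:
    """Per-protomer ddG values of the hexamer and their total."""

    ddg_per_protomer: np.ndarray  # 6 values, kcal/mol
    se_per_protomer: np.ndarray
    total_ddg: float
    total_se: float
    fold_change: float
    fold_change_power_of_ten: int
    temperature: float


def exp_estimator(work: np.ndarray, temperature: float) -> float:
    """One-sided exponential-averaging free energy, kcal/mol.

    dG = -RT ln <exp(-W/RT)>, computed with log-sum-exp stabilization.
    """
    w = np.asarray(work, dtype=float)
    if w.size < 1:
        raise ValueError("need at least one work sample")
    rt = kt(temperature)
    return float(-rt * (logsumexp(-w / rt) - np.log(w.size)))


class BarDivergence(Exception):
    """Raised when the BAR self-consistent equation has no bracketable root."""


def _bar_equation(dg: float, wf: np.ndarray, wr: np.ndarray,
                  beta: float, m: float) -> float:
    # logistic f(x) = 1/(1+e^x); expit(-x) = f(x)
    return (expit(-(beta * (wf - dg) + m)).sum()
            - expit(-(beta * (wr + dg) - m)).sum())


def _bar_point(wf: np.ndarray, wr: np.ndarray, temperature: float) -> float:
    beta = 1.0 / kt(temperature)
    m = np.log(wf.size / wr.size)
    lo = min(wf.min(), -wr.max()) - 1.0
    hi = max(wf.max(), -wr.min()) + 1.0
    flo = _bar_equation(lo, wf, wr, beta, m)
    fhi = _bar_equation(hi, wf, wr, beta, m)
    for _ in range(60):
        if flo * fhi <= 0:
            break
        lo, hi = lo - (hi - lo), hi + (hi - lo)
        flo = _bar_equation(lo, wf, wr, beta, m)
        fhi = _bar_equation(hi, wf, wr, beta, m)
    else:
        raise BarDivergence("work distributions do not bracket a root")
    return float(brentq(_bar_equation, lo, hi, args=(wf, wr, beta, m),
                        xtol=1e-9))


def bar_estimator(forward: np.ndarray, reverse: np.ndarray,
                  temperature: float, n_boot: int = 200,
                  seed: int = 0) -> tuple[float, float]:
    """Bennett acceptance ratio estimate of one window's dG, kcal/mol.

    Solves the self-consistent equation
    ``sum_F f(beta(W_F - dG) + M) = sum_R f(beta(W_R + dG) - M)`` with f the
    logistic function and M = ln(n_F/n_R), by bracketed root finding to
    1e-9 kcal/mol. The standard error is a seeded bootstrap over samples in
    both directions (0 when all work values are constant).
    """
    wf = np.asarray(forward, dtype=float)
    wr = np.asarray(reverse, dtype=float)
    if wf.size < 2 or wr.size < 2:
        raise ValueError("both directions need >= 2 samples")
    dg = _bar_point(wf, wr, temperature)
    if n_boot <= 0 or (np.ptp(wf) == 0 and np.ptp(wr) == 0):
        return dg, 0.0
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bf = rng.choice(wf, wf.size)
        br = rng.choice(wr, wr.size)
        try:
            boots[b] = _bar_point(bf, br, temperature)
        except BarDivergence:
            boots[b] = np.nan
    se = float(np.nanstd(boots, ddof=1))
    return dg, se


def combine_leg(per_window: list[tuple[float, float]],
                label: str = "complex") -> FreeEnergyLeg:
    """Sum window free energies into a leg; s.e. in quadrature."""
    if not per_window:
        raise ValueError("need at least one window")
    dgs = np.array([d for d, _ in per_window], dtype=float)
    ses = np.array([s for _, s in per_window], dtype=float)
    return FreeEnergyLeg(label=label, dg=float(dgs.sum()),
                         se=float(np.sqrt(np.sum(ses ** 2))),
                         per_window=list(per_window))


def estimate_leg(samples: WindowWorkSamples, label: str = "complex",
                 n_boot: int = 200, seed: int = 0) -> FreeEnergyLeg:
    """BAR on every window, then :func:`combine_leg`."""
    per_window = []
    for i in range(samples.n_windows):
        dg, se = bar_estimator(samples.forward[i], samples.reverse[i],
                               samples.temperature, n_boot=n_boot,
                               seed=seed + i)
        per_window.append((dg, se))
    return combine_leg(per_window, label=label)


def thermo_cycle(dg_complex: FreeEnergyLeg, dg_free: FreeEnergyLeg,
                 ) -> tuple[float, float]:
    """ddG = dG_complex - dG_free (positive: mutation weakens binding)."""
    ddg = dg_complex.dg - dg_free.dg
    se = float(np.hypot(dg_complex.se, dg_free.se))
    return float(ddg), se


def fold_change(ddg: float, temperature: float) -> float:
    """Binding-affinity fold change exp(ddG/RT)."""
    return float(np.exp(ddg / kt(temperature)))


def aggregate_protomers(ddg_list, temperature: float = 310.0,
                        se_list=None) -> ProtomerContributions:
    """Sum six per-protomer ddG contributions of the hexamer.

    Residues at the mutated position on different protomers do not interact,
    so the total binding free-energy difference is the plain sum. The fold
    change exp(total/RT) is also reported rounded to the nearest power of
    ten (the order-of-magnitude change in binding constant).
    """
    ddg = np.asarray(ddg_list, dtype=float)
    if ddg.shape != (6,):
        raise ValueError("exactly six per-protomer values are required")
    se = (np.zeros(6) if se_list is None
          else np.asarray(se_list, dtype=float))
    if se.shape != (6,):
        raise ValueError("se_list must have six entries")
    total = float(ddg.sum())
    fc = fold_change(total, temperature)
    power = int(round(np.log10(fc))) if fc > 0 else 0
    return ProtomerContributions(
        ddg_per_protomer=ddg, se_per_protomer=se, total_ddg=total,
        total_se=float(np.sqrt(np.sum(se ** 2))), fold_change=fc,
        fold_change_power_of_ten=10 ** power, temperature=temperature)
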