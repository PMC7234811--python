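"""Package-wide exceptions and warning categories."""


class KinbindError(Exception):
    """Base class for all package errors."""


class InvalidStateError(KinbindError):
    """A species state or rate set contains non-finite or otherwise invalid values."""


class SolverError(KinbindError):
    """The ODE integrator failed; carries the solver diagnostic message."""


class NumericalInstabilityError(KinbindError):
    """A concentration went negative beyond the solver tolerance band."""


class DegenerateEquilibriumError(KinbindError):
    """No complex can form at equilibrium (e.g. kb = 0), so the normalised
    fluorescence of the observation model is undefined."""


class InsufficientDataError(KinbindError):
    """Fewer data points than the requested fit can support."""


class FitFailureError(KinbindError):
    """A nonlinear fit failed to converge; carries per-start diagnostics."""


class NoOverlapError(KinbindError):
    """Two residue-indexed tables share no residues."""


class KinbindWarning(UserWarning):
    """Base class for all package warnings."""


class DegeneratePhasesWarning(KinbindWarning):
    """Two recovered exponential rates are within 5% of each other."""


class NoDecayWarning(KinbindWarning):
    """A transient carries no resolvable amplitude."""


class AbsorbingStateWarning(KinbindWarning):
    """k_-r = 0 with k_r > 0: the rearranged complex is absorbing."""


class DisconnectedStateWarning(KinbindWarning):
    """A microstate has no outgoing transition counts at the chosen lag."""


class ReducibleChainWarning(KinbindWarning):
    """The estimated Markov chain is not irreducible."""


class ExtrapolationWarning(KinbindWarning):
    """A fitted half-saturation point lies outside the sampled range."""


class PseudoFirstOrderWarning(KinbindWarning):
    """Titrant concentration below 5x the fixed partner: the pseudo-first-order
    reading of the phase rates is weak there."""


class IllDeterminedWarning(KinbindWarning):
    """A fitted parameter is not constrained by the sampled design."""
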