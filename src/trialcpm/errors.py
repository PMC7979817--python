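"""Exception types shared across the pipeline."""


class TrialCpmError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(TrialCpmError):
    """A configuration value violates an invariant; message names the violation."""


class WindowError(TrialCpmError):
    """A trial window cannot be extracted (e.g. probe onset earlier than window)."""


class DegenerateModelError(TrialCpmError):
    """The strength model cannot be fit (constant predictor, empty mask, too few trials)."""


class MissingEdgeError(TrialCpmError):
    """A masked edge carries a missing value for a trial whose strength was requested."""


class AtlasMismatchError(TrialCpmError):
    """Two objects disagree on the edge universe (node count / atlas)."""


class CollinearityError(TrialCpmError):
    """Covariate design matrix is rank deficient."""
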