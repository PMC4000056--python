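"""Exception and warning hierarchy."""


class CharDirError(Exception):
    """Base class for all chardir errors."""


class InputError(CharDirError):
    """Malformed or inconsistent user input (unknown ids, bad files, bad parameters)."""


class DesignError(CharDirError):
    """Invalid two-class design (overlapping classes, class size < 2, ...)."""


class DegenerateDataError(CharDirError):
    """Data carry no usable variance for the requested computation."""


class ZeroDirectionError(CharDirError):
    """The class means coincide: there is no differential signal to orient on."""


class CharDirWarning(UserWarning):
    """Base warning class."""


class SmallClassWarning(CharDirWarning):
    """A class has fewer than three replicates; results may be unstable."""


class EmptyIntersectionWarning(CharDirWarning):
    """A gene set shares no members with the measured gene universe."""
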