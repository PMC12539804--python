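"""Exception hierarchy shared across the toolkit.

Exit-code mapping used by the command line interface:
config problems -> 2, input/parse problems -> 3, numerical degeneracy -> 4.
"""


class TwistgateError(Exception):
    """Base class for all toolkit errors."""

    exit_code = 1


class ConfigError(TwistgateError):
    """Invalid or inconsistent run configuration."""

    exit_code = 2


class InputError(TwistgateError):
    """Problems with input files or in-memory inputs (parse, shape, units)."""

    exit_code = 3


class ParseError(InputError):
    """Malformed record in a text input; message names the line/row."""


class ShapeError(InputError):
    """Atom-count / frame-shape mismatch between related inputs."""


class SelectionError(InputError):
    """A selector matched nothing, or referenced absent chains/residues."""


class MappingError(InputError):
    """Residue -> domain/unit mapping is incomplete or ambiguous."""


class ParameterError(InputError):
    """Interaction parameters missing or invalid for some atom."""


class UnitError(InputError):
    """Unknown or unsupported physical unit."""


class DegenerateGeometryError(TwistgateError):
    """Geometry does not determine the requested quantity (collinear sets,
    axis-parallel helices, on-axis rotation groups, degenerate fits)."""

    exit_code = 4


class FitError(DegenerateGeometryError):
    """Regression abscissa degenerate; no fit possible."""
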