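"""Exception hierarchy shared across the package."""


class FFDatError(Exception):
    """Base class for all package errors."""


class TagError(FFDatError, ValueError):
    """Malformed tag text or invalid tag usage."""


class RegistryError(FFDatError, KeyError):
    """Unknown potential-function (section, ID) or group lookup."""


class FormatError(FFDatError, ValueError):
    """Unreadable or structurally invalid database / workbook / molfile."""


class DatasetValidationError(FFDatError, ValueError):
    """A dataset failed validation where a valid one is required."""

    def __init__(self, issues):
        self.issues = list(issues)
        super().__init__(
            "dataset has %d validation error(s): %s"
            % (len(self.issues), "; ".join(str(i) for i in self.issues))
        )


class StructureError(FFDatError, ValueError):
    """Chemically impossible molecular graph (e.g. multivalent hydrogen)."""


class TypingError(FFDatError, ValueError):
    """A site could not be assigned a functional group or tag."""


class ResolutionError(FFDatError, ValueError):
    """Base for term-resolution failures."""


class UnparameterizedTermError(ResolutionError):
    """No dataset record matches an enumerated term."""


class AmbiguousResolutionError(ResolutionError):
    """Two or more records tie at maximal specificity for a term."""
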