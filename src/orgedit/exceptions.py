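"""Exception hierarchy. Exit codes: input errors → 2, configuration errors → 3."""


class OrgeditError(Exception):
    """Base class for all orgedit errors."""

    exit_code = 1


class InputError(OrgeditError):
    """Malformed or inconsistent input data (alignments, references, tables)."""

    exit_code = 2


class ConfigError(OrgeditError):
    """Invalid configuration or parameter values."""

    exit_code = 3


class UndefinedExtentError(OrgeditError):
    """Editing extent requested at a site with no C or T coverage."""

    exit_code = 2
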