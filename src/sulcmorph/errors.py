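"""Package exceptions, mapped to CLI exit codes by sulcmorph.cli."""


class ConfigError(ValueError):
    """Invalid configuration (CLI exit code 2)."""


class DataError(RuntimeError):
    """Invalid or inconsistent data (CLI exit code 3)."""
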