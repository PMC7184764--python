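"""Shared pytest configuration.

Test data is generated programmatically; the expensive desk-scale
pipeline fixtures live module-scoped in test_acceptance.py so they are
built only when that module runs.
"""
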