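{"type": "grid", "m": 25, "lo": 0.0, "hi": 1.0}
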