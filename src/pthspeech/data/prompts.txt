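1. The supermarket chain shut down because of poor management.
2. Much more money must be donated to make this department succeed.
3. In this famous coffee shop, they serve the best donuts in town.
4. The chairman decided to pave over the shopping center garden.
5. The standards committee met this afternoon in an open meeting.
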