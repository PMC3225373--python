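library	raw_reads	adapter_removed_total	adapter_removed_unique	filtered_total	filtered_unique
juvenile	195149	191257	89945	105794	71824
adult	289959	280927	66978	63905	47408
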