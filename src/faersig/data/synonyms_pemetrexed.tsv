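raw	canonical
ALIMTA	pemetrexed
PEMETREXED	pemetrexed
Pemetrexed Disodium	pemetrexed
PEMETREXED DISODIUM HEMIPENTAHYDRATE	pemetrexed
PEMETREXED DISODIUM HEPTAHYDRATE	pemetrexed
PEMFEXY	pemetrexed
CIPLATIN	cisplatin
CISPLATIN	cisplatin
PLATINOL	cisplatin
CARBOPLATIN	carboplatin
PARAPLATIN	carboplatin
KEYTRUDA	pembrolizumab
PEMBROLIZUMAB	pembrolizumab
AVASTIN	bevacizumab
BEVACIZUMAB	bevacizumab
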