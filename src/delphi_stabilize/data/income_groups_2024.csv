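country,income_group
Austria,High Income Country
Belgium,High Income Country
Bulgaria,High Middle-Income Country
Croatia,High Income Country
Czechia,High Income Country
Denmark,High Income Country
Estonia,High Income Country
Finland,High Income Country
France,High Income Country
Germany,High Income Country
Greece,High Income Country
Hungary,High Income Country
Iceland,High Income Country
Ireland,High Income Country
Italy,High Income Country
Latvia,High Income Country
Lithuania,High Income Country
Netherlands,High Income Country
Norway,High Income Country
Poland,High Income Country
Portugal,High Income Country
Romania,High Income Country
Serbia,High Middle-Income Country
Slovakia,High Income Country
Slovenia,High Income Country
Spain,High Income Country
Sweden,High Income Country
Switzerland,High Income Country
Ukraine,Low Middle-Income Country
United Kingdom,High Income Country
Argentina,High Middle-Income Country
Australia,High Income Country
Bangladesh,Low Middle-Income Country
Brazil,High Middle-Income Country
Canada,High Income Country
Chile,High Income Country
China,High Middle-Income Country
Colombia,High Middle-Income Country
Egypt,Low Middle-Income Country
Ethiopia,Low Income Country
Ghana,Low Middle-Income Country
India,Low Middle-Income Country
Indonesia,High Middle-Income Country
Iran,Low Middle-Income Country
Japan,High Income Country
Kenya,Low Middle-Income Country
Malawi,Low Income Country
Malaysia,High Middle-Income Country
Mexico,High Middle-Income Country
Nepal,Low Middle-Income Country
New Zealand,High Income Country
Nigeria,Low Middle-Income Country
Pakistan,Low Middle-Income Country
Peru,High Middle-Income Country
Philippines,Low Middle-Income Country
Saudi Arabia,High Income Country
Singapore,High Income Country
South Africa,High Middle-Income Country
South Korea,High Income Country
Tanzania,Low Middle-Income Country
Thailand,High Middle-Income Country
Turkey,High Middle-Income Country
Uganda,Low Income Country
United States,High Income Country
Vietnam,Low Middle-Income Country
Zambia,Low Income Country
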