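country,region
Austria,Europe
Belgium,Europe
Bulgaria,Europe
Croatia,Europe
Czechia,Europe
Denmark,Europe
Estonia,Europe
Finland,Europe
France,Europe
Germany,Europe
Greece,Europe
Hungary,Europe
Iceland,Europe
Ireland,Europe
Italy,Europe
Latvia,Europe
Lithuania,Europe
Netherlands,Europe
Norway,Europe
Poland,Europe
Portugal,Europe
Romania,Europe
Serbia,Europe
Slovakia,Europe
Slovenia,Europe
Spain,Europe
Sweden,Europe
Switzerland,Europe
Ukraine,Europe
United Kingdom,Europe
Argentina,Rest of the World
Australia,Rest of the World
Bangladesh,Rest of the World
Brazil,Rest of the World
Canada,Rest of the World
Chile,Rest of the World
China,Rest of the World
Colombia,Rest of the World
Egypt,Rest of the World
Ethiopia,Rest of the World
Ghana,Rest of the World
India,Rest of the World
Indonesia,Rest of the World
Iran,Rest of the World
Japan,Rest of the World
Kenya,Rest of the World
Malawi,Rest of the World
Malaysia,Rest of the World
Mexico,Rest of the World
Nepal,Rest of the World
New Zealand,Rest of the World
Nigeria,Rest of the World
Pakistan,Rest of the World
Peru,Rest of the World
Philippines,Rest of the World
Saudi Arabia,Rest of the World
Singapore,Rest of the World
South Africa,Rest of the World
South Korea,Rest of the World
Tanzania,Rest of the World
Thailand,Rest of the World
Turkey,Rest of the World
Uganda,Rest of the World
United States,Rest of the World
Vietnam,Rest of the World
Zambia,Rest of the World
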